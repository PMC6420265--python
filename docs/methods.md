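# Methods

This note records the models and conventions behind `pirnakit`, the defaults
that matter, and the limits of what the synthetic tests demonstrate.

## The biological setting

A tandem array of transgenes can exist in two heritable epigenetic states of
identical DNA sequence: an inactive epiallele (OFF, no piRNA production, a
homologous reporter is expressed) and an active one (ON, the locus behaves as
a germline piRNA cluster and silences the reporter). The package quantifies
the two observable faces of this system: the small-RNA sequencing signature
of an activated cluster, and the transgenerational population dynamics of the
OFF → ON conversion.

## Read processing

**Adapter trimming.** Small-RNA inserts (18–30 nt) are shorter than the
sequencing read, so every read runs into the 3′ library adapter. A read is
truncated at the leftmost position where its remainder matches a prefix of
the adapter of at least `min_match` (default 6) bases, or contains the full
adapter. The default trades a ~0.5% chance of truncating at a spurious
6-mer against leaving adapter bases on short inserts; spuriously truncated
reads remain exact sub-reads of the true insert and still map correctly.
Trimming is idempotent. A read that is pure adapter raises and is dropped by
`trim_library`.

**Mapping.** References here are desk-scale (units to a few hundred kb), so
the mapper favours exactness over throughput: candidate starts come from a
pigeonhole split (with ≤ 1 substitution at least one half of the read matches
exactly and is located with `str.find`), and every candidate is verified by
Hamming distance. This is provably equivalent to an exhaustive per-position
scan — the test suite asserts the equivalence against a vectorised
brute-force oracle — and reports *all* placements on both strands.
Coordinates are 0-based half-open on the forward reference; a minus-strand
hit is a placement of the read's reverse complement, and its 5′ end is its
highest coordinate. Reads containing N are skipped and counted, never
errors. Indels and quality-aware trimming are out of scope.

**Multi-mappers.** Reads from a tandem array hit every copy. Downstream
analyses follow two conventions: 23–29-nt (piRNA) analyses drop multi-mappers
entirely (`unique_mappers`), whole-library size distributions may weight them
1/n (`multimapper_weights`). For signature analyses, reads are mapped against
a single repeat unit, which collapses the copies and makes array-derived
reads single-placement.

## Signature statistics

**Size distributions** count aligned instances per (length, strand) over
18–30 nt. **Normalisation** scales by 1e6 / normaliser, where the normaliser
is either the miRNA-matching read count (spike-in style) or the
genome-matching total; both modes are carried so every report can state its
provenance. A zero normaliser is an error naming the library.

**Ping-pong signature.** For every sense/antisense pair of 23–29-nt hits
whose 5′ ends overlap by i nt (plus 5′ at p, minus 5′ at q: i = q − p + 1),
the pair count O(i) is accumulated for i = 1..29, then standardised,
z(i) = (O(i) − mean O)/sd O. Conventions, each switchable:

* pairs are counted over aligned read instances (duplicated reads carry
  abundance); `collapse=True` counts distinct 5′-position pairs once;
* sd is the population sd over the 29 values (they are the whole population
  of overlaps of interest); `sample_sd=True` uses n−1. z sums to zero either
  way, and a flat O yields an all-NaN z rather than zeros;
* both mates of a 10-nt pair enter the 10A denominator.

**1U / 10A.** 1U is the percentage of aligned 23–29-nt instances whose first
nucleotide (read 5′→3′) is U; 10A the percentage of 10-nt-paired instances
with A at position 10. Empty denominators report NaN ("n.d."), mirroring
size classes too sparse to call.

At high read density the 10A estimate is diluted: reads not emitted as pairs
still engage in chance 10-nt overlaps, and their 10th base is essentially
uniform (~25% A). On a library of 10⁴ piRNAs over a 1.5-kb unit roughly a
third of engaged reads are chance-engaged, pulling a designed 90% down to
~70%. This is a property of the statistic, not a defect; the generator's
bias is recovered to ±2% when every read is a designed pair-mate.

## Window scan

Unique 23–29-nt hits from two libraries are tiled into non-overlapping 50-kb
windows (last window truncated), assigned by 5′-end coordinate — a partition,
no fractional overlap splitting. Per-window normalised counts become
densities per kb. Background is removed by a density floor (default
> 5 piRNAs/kb); the floor can demand the threshold in *either* library
(default) or in *both*. The literal both-libraries reading cannot detect a
locus silent in the first library — the very event of interest — so `either`
is the default and `both` ships for the literal behaviour. Differential
windows are scored by log2((count_b + 1)/(count_a + 1)); the pseudocount of
1 keeps zero-count OFF windows finite and is conventional. The flagging
threshold (default 8.5) is a caller parameter, not a fitted constant.

## Conversion and contingency statistics

Egg-chamber totals are estimated as mounted ovaries × 60 (3–4 chambers per
ovariole × 16–18 ovarioles). Repression frequencies are plain percentages
with a Wilson 95% interval attached — Wilson rather than Wald because
numerators of 0 against totals near 1000 are routine here and Wald collapses
at the boundary. The interval is an addition of this package; upstream
reports typically carry none.

Group comparisons use the Pearson homogeneity χ² (`scipy.stats`), with the
Yates continuity correction on 2×2 tables behind an explicit flag, default
off. Published small-count comparisons in this literature mix both
conventions, so every result records which was used. The Yates statistic
never exceeds the uncorrected one; both are invariant under row/column
permutation.

## qPCR arithmetic

Absolute quantification: copies = mass · N_A / (length · 650), with 650
g/mol per base pair of dsDNA. Standard curves are least-squares fits of Cq
on log10(quantity) over ≥ 3 distinct dilutions; efficiency = 10^(−1/slope) − 1
(slope −3.3219 ⇔ 100%); starting quantities (Sq) invert the fitted line, and
meanSq is the arithmetic mean of technical triplicates. Strand-specific RT
quantities subtract the no-primer control and are floored at zero with an
`at_background` flag (negative differences have no physical reading).
ChIP enrichment is (IP/input) rescaled by the mean (IP/input) of reference
regions of known constitutive enrichment. Group comparisons use the
equal-variance Student t-test, Welch behind a flag.

## The conversion simulator

A two-state (OFF/ON) epiallele propagates along maternal lines. Per female
and generation at 29 °C with the homologous transcribed target present, each
of K/m germline progenitors (K = 120 chambers = 2 ovaries × 60, m =
`cluster_size`) converts independently with probability `c_event`; a
converted progenitor yields m ON egg chambers. At 25 °C, or without the
target, conversion probability is exactly zero — a hard model constraint,
matching the observation that neither condition ever yielded conversion.
Each offspring develops from a uniformly drawn maternal chamber and inherits
its state; an ON chamber (or an ON mother) transmits ON with probability
`paramutation_prob` (default 1: the converted state is fully paramutagenic
and maternally absorbing). Paternal transmission is structurally absent.

Design choices where the data give no mechanism: offspring-from-random-
chamber is the simplest map from ovarian mosaicism to progeny; partial vs
complete repression of offspring is not modelled mechanistically; clustering
is a free parameter, default m = 1. The motivation for exposing m at all is
a reconciliation problem: a per-chamber rate of 0.027 under independent
chambers predicts 1 − 0.973¹²⁰ ≈ 96% of females with at least one converted
chamber, whereas female-level observations sit near 72%; progenitor-level
clustering lowers the female-level prediction without changing the expected
chamber count. This is model exploration, not a fitted claim.

**Rate recovery.** `recover_rate` is the binomial MLE on per-female
converted-chamber counts: successes/m over K/m trials per female, with the
usual binomial standard error; all-zero data report 0 with the one-sided
95% upper bound 1 − 0.05^(1/n). Note the chamber-count MLE's *point
estimate* is invariant to the assumed m (E[chambers] = cK regardless) — only
its SE depends on m. The cluster-misspecification hazard lives in
female-level inference: inverting the female conversion fraction
1 − (1−c)^(K/m) while assuming m = 1 when the truth is m underestimates c
about m-fold (`rate_from_female_fraction`; tested at m = 5).

`simulate_lineage` iterates females_sampled mothers per generation with
multinomial resampling from the offspring pool — drift from small samples is
deliberate and reproduces high between-line variance in conversion dynamics;
variance shrinks as the sample grows (tested at 10× sampling).

## Synthetic data: what it emulates and what it does not

The generator produces a toy chromosome with an n-copy tandem repeat
(default 7 identical units of 1 kb at a configurable insertion point, a
convergent flanking gene annotated on the opposite strand), a disjoint decoy
contig carrying 40 fixed "mature miRNAs" (21–23 nt) as the normaliser class,
and libraries mixing 23–29-nt piRNAs (unimodal length profile peaking at
25–26 nt, 1U-biased, a configurable fraction emitted as exact-10-nt-overlap
ping-pong pairs with 10A-biased partners), 21-nt strand-balanced siRNAs and
miRNA reads. Every read is emitted as a 50-cycle sequencing read — insert,
then the adapter, adapter-padded — so trimming is exercised genuinely.
Identical specs give byte-identical FASTQ.

One structural constraint is worth stating: ping-pong mates are perfect
reverse complements over the same locus, so one mate's 1U and the other's
10A are the same reference base and cannot be biased independently. In this
generator `a10_bias` controls both designed bases of every pair (paired-read
1U therefore equals `a10_bias`), and `u1_bias` governs unpaired piRNAs; the
two defaults coincide at 0.9, so overall 1U ≈ u1_bias in mixed libraries.

Not emulated: sequencing errors and quality variation (qualities are
constant "I"), real genome or miRBase content, transposon families, piRNA
biogenesis preferences beyond 1U/10A and length, cross-contamination.
Passing tests therefore demonstrate that the statistics recover controlled
composition from structurally realistic read sets — not performance on real
libraries with error, bias and repeat structure beyond a single tandem
array.

## Problem sizes and tolerances

Statistical recovery tests use binomial/multinomial 3-SE bands at their
stated n; closed-form identities use 1e-9 absolute tolerances. Default test
and acceptance scales — 10⁴-piRNA libraries on a 1.5-kb unit, a 250-kb
genome with 50-kb windows for the scan, 10⁴ simulated females, 200 reads
against 10 kb for the mapper-oracle equivalence — keep the whole suite
around 20 s and the acceptance script under 10 s on one CPU while leaving
every estimator's sampling error well inside its assertion band.
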