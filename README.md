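# pirnakit

Quantitative machinery for detecting the activation of a piRNA-producing
locus from small-RNA sequencing data, and for modelling how the activated
state spreads through generations.

A tandem transgene array in the *Drosophila* germline can exist in two
heritable epigenetic states of identical DNA sequence: OFF (no piRNAs, a
homologous reporter is expressed) and ON (the locus behaves as a germline
piRNA cluster and silences the reporter). `pirnakit` implements the analysis
stack used to characterise such epialleles and their environmentally induced
conversion, for computational biologists working with small-RNA libraries
and transgenerational silencing assays:

* **Read processing** — 3′ adapter trimming, exact 0/1-mismatch placement of
  reads on desk-scale references on both strands, 18–29-nt length filters
  and unique-mapper extraction (reads from an n-copy tandem array hit every
  copy and are dropped from unique analyses).
* **Library profiles** — size/strand distributions and per-position 5′-end
  coverage, normalised to one million miRNA-matching or genome-matching
  reads (rpm).
* **Ping-pong signature** — for sense/antisense 23–29-nt read pairs whose 5′
  ends overlap by *i* nt, pair counts O(i) for i = 1..29 standardised as

      z(i) = (O(i) − mean O) / sd O

  with the 1U fraction (reads starting with uridine) and the 10A fraction
  (adenine at position 10 among 10-nt-paired reads). A piRNA cluster engaged
  in ping-pong amplification shows a unique z peak at i = 10.
* **Window scan** — unique 23–29-nt mappers from two libraries resampled
  into 50-kb windows, background-filtered at > 5 piRNAs/kb, and scored by
  log2((b + 1)/(a + 1)) to flag loci that newly produce piRNAs.
* **Conversion statistics** — repression frequencies with Wilson intervals,
  egg-chamber totals (ovaries × 60), Pearson homogeneity χ² with an explicit
  Yates-correction flag.
* **qPCR arithmetic** — absolute quantification
  (copies = mass·N_A/(length·650)), standard-curve fits with efficiency
  10^(−1/slope) − 1, strand-specific RT background subtraction, ChIP
  enrichment against reference regions, unpaired t-tests.
* **Conversion simulator** — a stochastic maternal-line model in which each
  of K/m germline progenitors of an OFF female converts with probability c
  per generation at 29 °C (never at 25 °C, never without a transcribed
  homologous target), converted progenitors yield m ON egg chambers, and ON
  transmits maternally with a paramutation probability (default 1).
* **Synthetic data** — seeded generators for toy tandem-locus genomes,
  FASTQ libraries with controlled piRNA/siRNA/miRNA composition, 1U/10A
  biases and ping-pong pairing, and qPCR plates; the test bed for everything
  above.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

The packaged demo simulates an OFF/ON library pair over a 250-kb toy
chromosome carrying a single-copy transgene insertion at 110 kb, then runs
trim → map → filter → ping-pong → window scan:

```sh
pirnakit run --config examples/demo_config.yaml --out demo_out
```

prints (reformatted):

```json
{
  "on_library": {
    "z10": 5.166897077888581,
    "u1_fraction": 88.975,
    "a10_fraction": 80.0705467372134,
    "n_23_29_hits": 4000
  },
  "windowscan": {
    "n_candidate_windows": 1,
    "n_flagged_windows": 1,
    "flagged": [
      {"chrom": "chr_syn", "start": 100000, "end": 150000, "log2_ratio": 20.9316}
    ]
  },
  "seed": 1
}
```

Reading: the ON library's 23–29-nt reads show the ping-pong hallmark — the
10-nt overlap class sits 5.2 standard deviations above the mean overlap
count, with 89% of reads starting with U and 80% of paired reads carrying
10A — and exactly one 50-kb window (the one containing the insertion at
110 kb) exceeds the log2-ratio threshold of 8.5 against the OFF library,
identifying the transgene locus as the only de-novo piRNA producer. The
same Python API is available directly (`pirnakit.cli.run_pipeline`, or the
individual modules `pirnakit.mapping`, `pirnakit.pingpong`,
`pirnakit.windows`, `pirnakit.simulate`, ...).

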