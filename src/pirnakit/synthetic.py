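"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of an ovarian small-RNA experiment on a
tandem-transgene locus: a toy chromosome carrying ``n_copies`` identical
repeat units (default seven, mirroring a seven-copy *P-lacZ-white* array)
next to a convergently transcribed flanking gene, plus a disjoint decoy
contig standing in for the miRNA complement.  Libraries mix three read
classes:

* piRNAs: 23-29 nt from the repeat block, 1U-biased, a configurable fraction
  emitted as sense/antisense ping-pong pairs whose 5' ends overlap by exactly
  10 nt with an A at position 10 of each mate's partner;
* siRNAs: 21 nt, strand-balanced, from the repeat block;
* miRNAs: exact copies of fixed mature sequences on the decoy contig (the
  normaliser class).

Every read is emitted as a fixed 50-cycle sequencing read: insert followed by
the 3' adapter, adapter-padded and truncated — so adapter trimming is a real
step, not a formality.  All randomness flows from ``numpy``'s PCG64 seeded
from the spec, and identical specs give byte-identical FASTQ output.

Because ping-pong mates are perfect reverse complements of the same locus,
the 1U of one mate and the 10A of the other are the same reference base:
for paired reads both biases are controlled by ``a10_bias``, while
``u1_bias`` governs unpaired piRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mapping import DEFAULT_ADAPTER, SmallRNARead, revcomp

NUCLEOTIDES = np.array(list("ACGT"))
READ_CYCLES = 50
DECOY_NAME = "mirna_decoy"
DECOY_LENGTH = 2000
N_DECOY_MIRNAS = 40


@dataclass(frozen=True)
class LocusSpec:
    """Geometry of the synthetic tandem-transgene locus."""

    n_copies: int = 7
    unit_length: int = 1000
    flank_gene_length: int = 2000
    flank_orientation: str = "convergent"
    chrom_length: int = 50_000
    insert_position: int = 10_000
    chrom_name: str = "chr_syn"

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.unit_length < 100:
            raise ValueError("unit_length must be >= 100")
        if self.flank_orientation not in ("convergent", "divergent"):
            raise ValueError("flank_orientation must be convergent or divergent")
        if self.insert_position < 0:
            raise ValueError("insert_position must be >= 0")
        if self.insert_position + self.n_copies * self.unit_length > self.chrom_length:
            raise ValueError("repeat block overlaps the chromosome end")

    @property
    def block_start(self) -> int:
        return self.insert_position

    @property
    def block_end(self) -> int:
        return self.insert_position + self.n_copies * self.unit_length


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def build_reference(
    spec: LocusSpec, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build the toy reference collection and its BED-like annotation.

    Returns ``(references, annotation)``: the chromosome with the tandem
    repeat block inserted (all copies identical, same orientation), a decoy
    miRNA contig, and 0-based half-open annotation records for the repeat
    block, each copy, and the flanking gene (opposite strand when
    convergent).
    """
    rng = np.random.default_rng(seed)
    backbone = _random_seq(rng, spec.chrom_length)
    unit = _random_seq(rng, spec.unit_length)
    block = unit * spec.n_copies
    chrom = backbone[: spec.block_start] + block + backbone[spec.block_end :]
    decoy = _random_seq(rng, DECOY_LENGTH)
    refs = {spec.chrom_name: chrom, DECOY_NAME: decoy}

    rows = [
        (spec.chrom_name, spec.block_start, spec.block_end, "transgene_array", "+"),
    ]
    for i in range(spec.n_copies):
        s = spec.block_start + i * spec.unit_length
        rows.append((spec.chrom_name, s, s + spec.unit_length, f"transgene_copy_{i}", "+"))
    flank_strand = "-" if spec.flank_orientation == "convergent" else "+"
    flank_end = min(spec.block_end + spec.flank_gene_length, spec.chrom_length)
    if flank_end > spec.block_end:
        rows.append((spec.chrom_name, spec.block_end, flank_end, "flank_gene", flank_strand))
    annotation = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])
    return refs, annotation


def unit_reference(refs: Mapping[str, str], spec: LocusSpec) -> dict[str, str]:
    """Single-copy transgene unit, the reference for signature analyses.

    Reads from a tandem array are inherently multi-mapping on the chromosome;
    mapping against one unit collapses the copies, as when small RNAs are
    matched to 'the transgene sequence'.
    """
    chrom = refs[spec.chrom_name]
    return {"transgene_unit": chrom[spec.block_start : spec.block_start + spec.unit_length]}


def decoy_mirnas(refs: Mapping[str, str]) -> list[str]:
    """The fixed mature miRNA sequences defined on the decoy contig."""
    decoy = refs[DECOY_NAME]
    seqs = []
    lengths = (21, 22, 23)
    for i in range(N_DECOY_MIRNAS):
        start = 10 + 45 * i
        L = lengths[i % 3]
        seqs.append(decoy[start : start + L])
    return seqs


def _default_length_weights() -> dict[int, float]:
    # unimodal piRNA size profile peaking at 25-26 nt
    return {23: 0.10, 24: 0.17, 25: 0.25, 26: 0.22, 27: 0.14, 28: 0.08, 29: 0.04}


@dataclass(frozen=True)
class LibrarySpec:
    """Composition of one synthetic small-RNA library."""

    n_pirna: int = 10_000
    n_sirna: int = 2_000
    n_mirna: int = 5_000
    pingpong_fraction: float = 0.5
    u1_bias: float = 0.9
    a10_bias: float = 0.9
    sense_fraction: float = 0.7
    pirna_length_weights: Mapping[int, float] = field(default_factory=_default_length_weights)
    adapter: str = DEFAULT_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pingpong_fraction", "u1_bias", "a10_bias", "sense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        w = dict(self.pirna_length_weights)
        if any(wt < 0 for wt in w.values()) or sum(w.values()) <= 0:
            raise ValueError("length weights must be nonnegative with positive sum")
        if any(L < 23 or L > 29 for L in w):
            raise ValueError("piRNA lengths must lie in 23..29")
        if self.pingpong_fraction > 0 and self.n_pirna < 2:
            raise ValueError("ping-pong pairs need n_pirna >= 2")


def _positions_by_class(chrom: str, lo: int, hi: int):
    """Split positions [lo, hi) of the repeat block by the bases that control
    1U/10A: (base at p is T?, base at p+9 is A?)."""
    classes: dict[tuple[bool, bool], list[int]] = {
        (a, b): [] for a in (True, False) for b in (True, False)
    }
    for p in range(lo, hi):
        classes[(chrom[p] == "T", chrom[p + 9] == "A")].append(p)
    return {k: np.array(v, dtype=int) for k, v in classes.items()}


def _pick(rng: np.random.Generator, pools: list[np.ndarray]) -> int:
    """Uniform draw from the first non-empty pool (fallbacks widen the class)."""
    for pool in pools:
        if len(pool):
            return int(pool[rng.integers(len(pool))])
    raise ValueError("repeat block too small to place reads")


def _sequencing_read(insert: str, adapter: str, cycles: int = READ_CYCLES) -> str:
    padded = insert + adapter * (cycles // len(adapter) + 2)
    return padded[:cycles]


def simulate_small_rna_library(
    refs: Mapping[str, str], locus: LocusSpec, spec: LibrarySpec
) -> list[SmallRNARead]:
    """Simulate one adapter-terminated small-RNA library over the locus.

    All inserts are exact substrings (or reverse complements of substrings)
    of the reference, so trimmed reads map back with zero mismatches.
    Deterministic: identical ``(refs, locus, spec)`` give identical output.
    """
    chrom = refs[locus.chrom_name]
    if not chrom:
        raise ValueError("empty reference")
    rng = np.random.default_rng(spec.seed)
    block_start, block_end = locus.block_start, locus.block_end
    if block_end - block_start < 80:
        raise ValueError("repeat block too short for 29-nt reads")

    lengths = np.array(sorted(spec.pirna_length_weights), dtype=int)
    lw = np.array([spec.pirna_length_weights[L] for L in lengths], dtype=float)
    lw = lw / lw.sum()

    # anchor classes for ping-pong pairs: initiator 5' at p (sense), responder
    # 5' at q = p + 9 (antisense); both mates' 1U/10A are set by chrom[p] and
    # chrom[p + 9]
    anchor_classes = _positions_by_class(chrom, block_start + 20, block_end - 29)
    reads: list[SmallRNARead] = []

    n_pairs = int(round(spec.n_pirna * spec.pingpong_fraction / 2))
    n_unpaired = spec.n_pirna - 2 * n_pairs

    for i in range(n_pairs):
        want_t = rng.random() < spec.a10_bias  # responder 10A & initiator 1U
        want_a = rng.random() < spec.a10_bias  # initiator 10A & responder 1U
        pools = [
            anchor_classes[(want_t, want_a)],
            anchor_classes[(want_t, not want_a)],
            anchor_classes[(not want_t, want_a)],
            anchor_classes[(not want_t, not want_a)],
        ]
        p = _pick(rng, pools)
        L1 = int(rng.choice(lengths, p=lw))
        L2 = int(rng.choice(lengths, p=lw))
        q = p + 9
        initiator = chrom[p : p + L1]
        responder = revcomp(chrom[q - L2 + 1 : q + 1])
        reads.append(SmallRNARead(f"pi_pair{i:05d}_ini", _sequencing_read(initiator, spec.adapter)))
        reads.append(SmallRNARead(f"pi_pair{i:05d}_res", _sequencing_read(responder, spec.adapter)))

    # unpaired piRNAs: 5'-position classes by the base that determines 1U
    t_pos = np.array(
        [p for p in range(block_start, block_end - 29) if chrom[p] == "T"], dtype=int
    )
    nt_pos = np.array(
        [p for p in range(block_start, block_end - 29) if chrom[p] != "T"], dtype=int
    )
    a_pos = np.array(
        [q for q in range(block_start + 29, block_end) if chrom[q] == "A"], dtype=int
    )
    na_pos = np.array(
        [q for q in range(block_start + 29, block_end) if chrom[q] != "A"], dtype=int
    )
    for i in range(n_unpaired):
        L = int(rng.choice(lengths, p=lw))
        want_u = rng.random() < spec.u1_bias
        if rng.random() < spec.sense_fraction:
            p = _pick(rng, [t_pos, nt_pos] if want_u else [nt_pos, t_pos])
            insert = chrom[p : p + L]
        else:
            q = _pick(rng, [a_pos, na_pos] if want_u else [na_pos, a_pos])
            insert = revcomp(chrom[q - L + 1 : q + 1])
        reads.append(SmallRNARead(f"pi_un{i:06d}", _sequencing_read(insert, spec.adapter)))

    for i in range(spec.n_sirna):
        p = int(rng.integers(block_start, block_end - 21))
        insert = chrom[p : p + 21]
        if rng.random() < 0.5:
            insert = revcomp(insert)
        reads.append(SmallRNARead(f"si_{i:06d}", _sequencing_read(insert, spec.adapter)))

    matures = decoy_mirnas(refs)
    for i in range(spec.n_mirna):
        insert = matures[int(rng.integers(len(matures)))]
        reads.append(SmallRNARead(f"mi_{i:06d}", _sequencing_read(insert, spec.adapter)))

    return reads


def simulate_qpcr_plate(
    true_quantities: Mapping[str, float],
    efficiency: float = 0.9,
    noise_sd: float = 0.1,
    seed: int = 0,
    intercept: float = 38.0,
    n_replicates: int = 3,
    target: str = "target",
) -> pd.DataFrame:
    """Simulate technical-replicate Cq values for known starting quantities.

    Cq = intercept - log10(quantity) / log10(1 + efficiency) + N(0, noise_sd).
    Returns a tidy frame (sample, target, replicate, Cq).
    """
    if not 0.0 < efficiency <= 1.0:
        raise ValueError("efficiency must be in (0, 1]")
    if any(q <= 0 for q in true_quantities.values()):
        raise ValueError("quantities must be positive")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(1.0 + efficiency)
    rows = []
    for sample, q in true_quantities.items():
        for rep in range(1, n_replicates + 1):
            cq = intercept + slope * np.log10(q) + rng.normal(0.0, noise_sd)
            rows.append((sample, target, rep, cq))
    return pd.DataFrame(rows, columns=["sample", "target", "replicate", "Cq"])
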