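"""Ping-pong overlap signature and 1U/10A composition statistics.

The ping-pong amplification loop leaves a footprint in small-RNA libraries:
sense/antisense 23-29 nt read pairs whose 5' ends overlap by exactly 10 nt,
with a uridine at position 1 of one mate and an adenine at position 10 of the
other.  The signature is quantified by counting, for each possible 5' overlap
``i`` of 1..29 nt, the number of read pairs ``O(i)``, then standardising:

    z(i) = (O(i) - mean(O)) / sd(O)

For a plus-strand hit with 5' end ``p`` and a minus-strand hit with 5' end
``q`` (its highest coordinate), the overlap is ``i = q - p + 1``.

Defaults: pairs are counted over aligned read *instances* (duplicated reads
carry abundance signal); ``collapse=True`` counts distinct 5'-position pairs
once.  The standard deviation is the population sd over the 29 overlap
values; ``sample_sd=True`` switches to the n-1 form.  Both mates of a 10-nt
pair enter the 10A denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentHit

OVERLAP_RANGE = range(1, 30)
PIRNA_MIN, PIRNA_MAX = 23, 29


def first_u_fraction(
    hits: Sequence[AlignmentHit], reads: Mapping[str, str]
) -> float:
    """Percentage of aligned 23-29 nt read instances whose first nucleotide is U.

    Computed on the read sequence 5'->3' (U is sequenced as T).  Returns NaN
    ("n.d.") on an empty hit set — mirroring size classes too sparse to call.
    """
    n = 0
    n_u = 0
    for h in hits:
        seq = reads[h.read_id]
        n += 1
        if seq[0] == "T":
            n_u += 1
    if n == 0:
        return float("nan")
    return 100.0 * n_u / n


def _five_prime_counters(
    hits: Sequence[AlignmentHit], collapse: bool = False
) -> tuple[Counter, Counter]:
    """Instance counts of 5'-end positions keyed by (reference, pos)."""
    plus: Counter = Counter()
    minus: Counter = Counter()
    for h in hits:
        key = (h.reference, h.five_prime)
        tgt = plus if h.strand == "+" else minus
        if collapse:
            tgt[key] = 1
        else:
            tgt[key] += 1
    return plus, minus


def overlap_pair_counts(
    hits: Sequence[AlignmentHit], collapse: bool = False
) -> dict[int, int]:
    """Count sense/antisense pairs per 5'-overlap of 1..29 nt.

    Each (plus instance, minus instance) combination with overlap ``i``
    contributes one pair; with ``collapse=True`` multiplicities at a 5'
    position are ignored.
    """
    plus, minus = _five_prime_counters(hits, collapse)
    O = {i: 0 for i in OVERLAP_RANGE}
    for (ref, p), np_ in plus.items():
        for i in OVERLAP_RANGE:
            nm = minus.get((ref, p + i - 1), 0)
            if nm:
                O[i] += np_ * nm
    return O


def overlap_zscores(O: Mapping[int, int], sample_sd: bool = False) -> np.ndarray:
    """Standardise O(1..29); all-NaN when sd is zero (flat signature)."""
    vals = np.array([O[i] for i in OVERLAP_RANGE], dtype=float)
    sd = vals.std(ddof=1 if sample_sd else 0)
    if sd == 0:
        return np.full(len(vals), np.nan)
    return (vals - vals.mean()) / sd


def paired_read_instances(
    hits: Sequence[AlignmentHit], overlap: int = 10
) -> list[AlignmentHit]:
    """Hit instances engaged in at least one pair at the given exact overlap.

    Both mates of each pair are returned (the default 10A denominator).
    """
    plus, minus = _five_prime_counters(hits)
    engaged: list[AlignmentHit] = []
    for h in hits:
        key = (h.reference, h.five_prime)
        if h.strand == "+":
            partner = (h.reference, h.five_prime + overlap - 1)
            if minus.get(partner, 0):
                engaged.append(h)
        else:
            partner = (h.reference, h.five_prime - overlap + 1)
            if plus.get(partner, 0):
                engaged.append(h)
    return engaged


def tenth_a_fraction(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, str],
    overlap: int = 10,
) -> float:
    """Percentage of 10-nt-paired read instances with A at position 10.

    Position 10 is read 5'->3' on the read sequence itself.  Returns NaN
    ("n.d.") when no pairs exist at the requested overlap.
    """
    engaged = paired_read_instances(hits, overlap)
    n = 0
    n_a = 0
    for h in engaged:
        seq = reads[h.read_id]
        if len(seq) < overlap:
            continue
        n += 1
        if seq[overlap - 1] == "A":
            n_a += 1
    if n == 0:
        return float("nan")
    return 100.0 * n_a / n


@dataclass(frozen=True)
class OverlapSignature:
    """Pair counts O(1..29), z-scores and 1U/10A composition of one library."""

    O: dict[int, int]
    z: np.ndarray
    u1_fraction: float
    a10_fraction: float
    n_reads: int
    n_paired_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overlap": list(OVERLAP_RANGE),
                "count": [self.O[i] for i in OVERLAP_RANGE],
                "z": self.z,
            }
        )


def signature(
    hits: Sequence[AlignmentHit],
    reads: Mapping[str, str],
    collapse: bool = False,
    sample_sd: bool = False,
) -> OverlapSignature:
    """Full ping-pong report for a set of 23-29 nt hits on one reference set."""
    pirna_hits = [h for h in hits if PIRNA_MIN <= h.read_length <= PIRNA_MAX]
    O = overlap_pair_counts(pirna_hits, collapse)
    z = overlap_zscores(O, sample_sd)
    engaged = paired_read_instances(pirna_hits)
    return OverlapSignature(
        O=O,
        z=z,
        u1_fraction=first_u_fraction(pirna_hits, reads),
        a10_fraction=tenth_a_fraction(pirna_hits, reads),
        n_reads=len(pirna_hits),
        n_paired_reads=len(engaged),
    )
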