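"""Size/strand distributions, rpm normalisation and 5'-end coverage profiles.

Two normalisation conventions are carried side by side: counts per million
miRNA-matching reads (spike-in style) and counts per million genome-matching
reads (rpm).  Both rescale by ``1e6 / normalizer_total`` and differ only in
what the normaliser counts, so the mode is recorded as metadata rather than
changing the arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentHit

NORMALIZATION_MODES = ("mirna_million", "genome_million")


def size_distribution(
    hits: Sequence[AlignmentHit],
    min_len: int = 18,
    max_len: int = 30,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Count hits per (read length, strand).

    ``weights`` maps read_id -> weight (e.g. 1/n_placements for
    multi-mappers); default weight is 1 per aligned instance.  Returns a tidy
    frame with one row per (length, strand) over the full requested range,
    zero-filled.  Antisense counts are kept positive here; rendering them as
    negative values is a plotting convention only.
    """
    lengths = range(min_len, max_len + 1)
    index = pd.MultiIndex.from_product([lengths, ["+", "-"]], names=["length", "strand"])
    acc = pd.Series(0.0, index=index)
    for h in hits:
        if min_len <= h.read_length <= max_len:
            w = 1.0 if weights is None else weights.get(h.read_id, 1.0)
            acc.loc[(h.read_length, h.strand)] += w
    out = acc.reset_index(name="count")
    return out


def normalize_rpm(
    counts: pd.Series | np.ndarray | float,
    normalizer_total: int,
    mode: str = "mirna_million",
    library: str = "library",
):
    """Scale counts to one million normaliser reads.

    Raises a ``ValueError`` naming the library when the normaliser is empty —
    a silent zero here would poison every downstream ratio.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if normalizer_total <= 0:
        raise ValueError(
            f"cannot normalize {library!r}: normalizer total is {normalizer_total}"
        )
    return counts * (1e6 / normalizer_total)


def add_rpm_column(
    dist: pd.DataFrame, normalizer_total: int, mode: str = "mirna_million",
    library: str = "library",
) -> pd.DataFrame:
    out = dist.copy()
    out["rpm"] = normalize_rpm(out["count"], normalizer_total, mode, library)
    out.attrs["normalization_mode"] = mode
    out.attrs["normalizer_total"] = normalizer_total
    return out


@dataclass
class CoverageProfile:
    """Per-position 5'-end counts on one reference, split by strand."""

    reference: str
    length: int
    plus: np.ndarray = field(repr=False)
    minus: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(self.length),
                "plus": self.plus,
                "minus": self.minus,
            }
        )


def coverage_profile(
    hits: Sequence[AlignmentHit], reference: str, ref_length: int
) -> CoverageProfile:
    """5'-end coverage on ``reference``.

    The 5' end of a minus-strand hit is its highest coordinate (``end - 1``).
    The sum over both tracks equals the number of contributing hits.
    """
    plus = np.zeros(ref_length, dtype=float)
    minus = np.zeros(ref_length, dtype=float)
    for h in hits:
        if h.reference != reference:
            continue
        p = h.five_prime
        if not 0 <= p < ref_length:
            raise ValueError(f"hit 5' end {p} outside reference of length {ref_length}")
        (plus if h.strand == "+" else minus)[p] += 1
    return CoverageProfile(reference, ref_length, plus, minus)
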