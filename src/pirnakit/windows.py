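"""Genome-window scan for loci that newly produce piRNAs between libraries.

Unique 23-29 nt mappers from two libraries (e.g. an inactive and an activated
epiallele) are resampled into non-overlapping 50-kb windows, converted to
normalised piRNA densities per kb, filtered against background, and compared
by log2 ratio.  A window whose ratio exceeds a caller-supplied threshold
(8.5 in the motivating analysis) is flagged as a de-novo piRNA producer.

The background filter has two readings.  ``mode="either"`` (default) keeps
windows above the density floor in at least one library — necessary to detect
a locus silent in the first library.  ``mode="both"`` is the literal
"in both libraries" reading, which can only re-score loci already active in
both.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentHit

DEFAULT_WIDTH = 50_000
DEFAULT_MIN_DENSITY = 5.0
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_LOG2_THRESHOLD = 8.5


def tile_genome(
    chrom_lengths: Mapping[str, int], width: int = DEFAULT_WIDTH
) -> pd.DataFrame:
    """Non-overlapping windows covering each chromosome; last one truncated."""
    if width < 1:
        raise ValueError("width must be >= 1")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom!r} has nonpositive length")
        for start in range(0, length, width):
            rows.append((chrom, start, min(start + width, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def assign_counts(
    hits: Sequence[AlignmentHit], windows: pd.DataFrame
) -> np.ndarray:
    """Raw hit count per window, assigning each hit by its 5'-end coordinate.

    Every hit on a tiled chromosome lands in exactly one window (the tiling is
    a partition); hits on untiled references raise.
    """
    index: dict[str, dict[int, int]] = {}
    for row_i, row in enumerate(windows.itertuples(index=False)):
        index.setdefault(row.chrom, {})[row.start] = row_i
    counts = np.zeros(len(windows), dtype=float)
    # windows are uniform-width except the truncated last one, so the window
    # start is floor(pos / width) * width
    width = int((windows["end"] - windows["start"]).max()) if len(windows) else 0
    for h in hits:
        if h.reference not in index:
            raise ValueError(f"hit on untiled reference {h.reference!r}")
        p = h.five_prime
        start = (p // width) * width
        try:
            counts[index[h.reference][start]] += 1
        except KeyError:
            raise ValueError(
                f"5' end {p} beyond tiled extent of {h.reference!r}"
            ) from None
    return counts


def window_densities(
    hits: Sequence[AlignmentHit],
    windows: pd.DataFrame,
    normalizer_total: int,
    suffix: str,
) -> pd.DataFrame:
    """Attach normalised counts and per-kb densities for one library.

    density = normalised count / (window width / 1000).
    """
    out = windows.copy()
    raw = assign_counts(hits, windows)
    norm = raw * (1e6 / normalizer_total)
    kb = (out["end"] - out["start"]) / 1000.0
    out[f"count_{suffix}"] = norm
    out[f"density_{suffix}"] = norm / kb
    return out


def candidate_windows(
    windows: pd.DataFrame,
    min_density: float = DEFAULT_MIN_DENSITY,
    mode: str = "either",
) -> pd.DataFrame:
    """Background filter: density floor in at least one library, or in both."""
    if mode not in ("either", "both"):
        raise ValueError(f"mode must be 'either' or 'both', got {mode!r}")
    a = windows["density_a"] > min_density
    b = windows["density_b"] > min_density
    keep = (a | b) if mode == "either" else (a & b)
    return windows[keep].reset_index(drop=True)


def log2_ratio(count_a: float, count_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((b + pc) / (a + pc)); positive when library b gained piRNAs."""
    return math.log2((count_b + pseudocount) / (count_a + pseudocount))


def scan(
    hits_a: Sequence[AlignmentHit],
    hits_b: Sequence[AlignmentHit],
    chrom_lengths: Mapping[str, int],
    normalizer_total_a: int,
    normalizer_total_b: int,
    width: int = DEFAULT_WIDTH,
    min_density: float = DEFAULT_MIN_DENSITY,
    mode: str = "either",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
) -> pd.DataFrame:
    """Full two-library window scan.

    Inputs should already be unique 23-29 nt mappers.  Returns a BED-like
    frame (chrom, start, end, count_a, count_b, density_a, density_b,
    log2_ratio, flagged) restricted to candidate windows.
    """
    windows = tile_genome(chrom_lengths, width)
    wa = window_densities(hits_a, windows, normalizer_total_a, "a")
    wb = window_densities(hits_b, windows, normalizer_total_b, "b")
    merged = wa.merge(wb, on=["chrom", "start", "end"])
    cand = candidate_windows(merged, min_density, mode)
    cand = cand.copy()
    cand["log2_ratio"] = [
        log2_ratio(a, b, pseudocount)
        for a, b in zip(cand["count_a"], cand["count_b"])
    ]
    cand["flagged"] = cand["log2_ratio"] > log2_threshold
    return cand
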