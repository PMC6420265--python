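"""Repression-frequency and contingency-table statistics for conversion scoring.

Epiallele conversion is scored in the ovary: the fraction of egg chambers (or
of whole females) showing reporter repression.  Totals are usually estimated,
not counted — an average of 60 egg chambers per mounted ovary (3-4 chambers
per ovariole, 16-18 ovarioles per ovary).  Group comparisons use the Pearson
homogeneity chi-square on r x c count tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

EGG_CHAMBERS_PER_OVARY = 60


def estimate_total_egg_chambers(
    n_ovaries: int, per_ovary: int = EGG_CHAMBERS_PER_OVARY
) -> int:
    """Estimated egg-chamber total from the number of mounted ovaries."""
    if n_ovaries < 0:
        raise ValueError("n_ovaries must be >= 0")
    return n_ovaries * per_ovary


@dataclass(frozen=True)
class RepressionCount:
    """Observed repression frequency with a Wilson 95% interval.

    The interval is an addition for downstream use (Wald misbehaves at the
    0/n boundary); the point estimate is the plain percentage.
    """

    n_repressed: int
    n_total: int
    frequency: float  # percent
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> str:
        """Frequency formatted to one decimal, e.g. '2.7%'."""
        return f"{self.frequency:.1f}%"


def repression_frequency(n_repressed: int, n_total: int) -> RepressionCount:
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_repressed <= n_total:
        raise ValueError("need 0 <= n_repressed <= n_total")
    lo, hi = proportion_confint(n_repressed, n_total, alpha=0.05, method="wilson")
    p = n_repressed / n_total
    # guard against round-off placing a boundary estimate just outside
    lo, hi = min(lo, p), max(hi, p)
    return RepressionCount(
        n_repressed=n_repressed,
        n_total=n_total,
        frequency=100.0 * p,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
    )


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p: float
    continuity_correction: bool


def homogeneity_chi2(
    table: Sequence[Sequence[int]], continuity_correction: bool = False
) -> Chi2Result:
    """Pearson homogeneity chi-square on an r x c count table.

    ``continuity_correction`` applies the Yates adjustment
    ``(|obs - exp| - 0.5)^2 / exp`` on 2x2 tables only (it has no standard
    extension beyond 2x2 and scipy ignores it there too).  Default off; the
    flag is first-class because published values mix both conventions.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins: a row or column sums to zero")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return Chi2Result(float(stat), int(df), float(p), continuity_correction)
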