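"""RT-qPCR quantification arithmetic: standard curves, strand-specific RT, ChIP.

Absolute quantification rests on a dilution series of a plasmid of known mass:
the molecule count of ``m`` grams of a ``L``-bp dsDNA is

    copies = m * N_A / (L * 650)

with Avogadro's number N_A and 650 g/mol as the average weight of a base pair.
Cq values regress linearly on log10(quantity); the slope gives the
amplification efficiency ``E = 10^(-1/slope) - 1`` (slope -3.3219 <=> 100%).
Starting quantities (Sq) come from inverting the fitted line; the mean of
technical triplicates (meanSq) is the working quantity throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

AVOGADRO = 6.022e23
MEAN_BP_WEIGHT = 650.0  # g/mol per base pair of dsDNA


def copies_from_mass(mass_g: float, length_bp: int) -> float:
    """Molecule count of ``mass_g`` grams of dsDNA of ``length_bp`` base pairs."""
    if mass_g < 0:
        raise ValueError("mass must be >= 0")
    if length_bp <= 0:
        raise ValueError("length must be > 0")
    return mass_g * AVOGADRO / (length_bp * MEAN_BP_WEIGHT)


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line Cq = slope * log10(quantity) + intercept."""

    slope: float
    intercept: float
    r2: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification efficiency; 1.0 means perfect doubling."""
        return 10 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit Cq on log10(known quantity) over a dilution series.

    Requires >= 3 distinct dilution points; a nonnegative slope (no
    amplification trend) is rejected.
    """
    qs = np.array([p[0] for p in points], dtype=float)
    cqs = np.array([p[1] for p in points], dtype=float)
    if (qs <= 0).any():
        raise ValueError("quantities must be positive")
    if len(np.unique(qs)) < 3:
        raise ValueError("need at least 3 distinct dilution points")
    res = stats.linregress(np.log10(qs), cqs)
    if res.slope >= 0:
        raise ValueError(f"nonnegative slope {res.slope:.3g}: not an amplification curve")
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def quantity_from_cq(curve: StandardCurve, cq: float) -> float:
    """Invert the standard curve: Sq = 10^((Cq - intercept) / slope)."""
    return 10 ** ((cq - curve.intercept) / curve.slope)


def mean_sq(replicates: Sequence[float]) -> float:
    """meanSq: arithmetic mean of technical replicate Sq values."""
    if len(replicates) == 0:
        raise ValueError("no replicates")
    return float(np.mean(replicates))


def relative_expression(mean_sq_gene: float, mean_sq_reference: float) -> float:
    """meanSq(gene) / meanSq(reference housekeeping gene)."""
    if mean_sq_reference <= 0:
        raise ValueError("reference meanSq must be > 0")
    return mean_sq_gene / mean_sq_reference


@dataclass(frozen=True)
class StrandQuantity:
    """Background-subtracted strand-specific quantity.

    The no-primer RT control measures unspecific amplification; a primed
    signal at or below it is floored at zero and flagged.
    """

    quantity: float
    at_background: bool


def strand_specific_quantity(
    mean_sq_primed: float, mean_sq_no_primer_control: float
) -> StrandQuantity:
    diff = mean_sq_primed - mean_sq_no_primer_control
    if diff <= 0:
        return StrandQuantity(0.0, True)
    return StrandQuantity(diff, False)


def chip_enrichment(
    ip_sq: float, input_sq: float, reference_region_ratios: Sequence[float]
) -> float:
    """Input-normalised IP signal, rescaled by reference heterochromatic regions.

    ``reference_region_ratios`` are the (ip/input) ratios of regions with
    known constitutive enrichment for the immunoprecipitated mark.
    """
    if input_sq <= 0:
        raise ValueError("input must be > 0")
    if len(reference_region_ratios) == 0:
        raise ValueError("need at least one reference region")
    ref = float(np.mean(reference_region_ratios))
    if ref <= 0:
        raise ValueError("reference region mean ratio must be > 0")
    return (ip_sq / input_sq) / ref


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Unpaired two-sided t-test (Student by default, Welch behind the flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))
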