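"""Plate-assay statistics for in-vitro validation of selected compounds.

Covers the arithmetic downstream of two colorimetric assays:

* CCK-8 cytotoxicity — optical density at 450 nm is proportional to live
  cell count; viability of a treated well is its (optionally
  blank-corrected) OD as a percentage of the control-group mean, and a
  treatment group is non-cytotoxic per ISO 10993-5 when its mean
  viability is >= 70% of control (inclusive).
* Griess nitrite — optical density at 550 nm maps to nitrite
  concentration (a proxy for NO release by inflamed chondrocytes)
  through a linear standard curve fitted by ordinary least squares.

Group means are compared with a two-tailed unpaired t-test (Student
pooled-variance by default, Welch by flag), with the usual significance
stars at p < 0.05 / 0.01 / 0.001 / 0.0001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StandardCurve",
    "GroupComparison",
    "viability_percent",
    "classify_cytotoxicity",
    "fit_standard_curve",
    "nitrite_concentration",
    "unpaired_t_test",
    "significance_stars",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted line od = slope * concentration + intercept (conc in uM)."""

    slope: float
    intercept: float


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    stars: str


def viability_percent(
    treatment_ods: Sequence[float],
    control_ods: Sequence[float],
    blank_od: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Per-replicate viability percentages and their group mean.

    viability = 100 * (od - blank) / (control_mean - blank). Blank
    correction defaults to none (blank 0). The control mean must exceed
    the blank.
    """
    treatment = np.asarray(treatment_ods, dtype=float)
    control_mean = float(np.mean(np.asarray(control_ods, dtype=float)))
    denom = control_mean - blank_od
    if denom <= 0:
        raise ValueError(
            f"control mean ({control_mean}) must exceed blank ({blank_od})"
        )
    pct = 100.0 * (treatment - blank_od) / denom
    return pct, float(pct.mean())


def classify_cytotoxicity(group_viability_pct: float) -> str:
    """ISO 10993-5 call on a treatment group's mean viability.

    ``noncytotoxic`` iff viability >= 70% of control (inclusive); the
    classification applies to the group mean, not to single replicates.
    """
    if not np.isfinite(group_viability_pct):
        raise ValueError("viability percentage must be finite")
    return "noncytotoxic" if group_viability_pct >= 70.0 else "cytotoxic"


def fit_standard_curve(
    points: Sequence[tuple[float, float]]
) -> StandardCurve:
    """Ordinary least-squares line through (concentration, od) standards."""
    conc = np.array([p[0] for p in points], dtype=float)
    od = np.array([p[1] for p in points], dtype=float)
    if np.unique(conc).size < 2:
        raise ValueError("standard curve needs >= 2 distinct concentrations")
    fit = stats.linregress(conc, od)
    if fit.slope == 0:
        raise ValueError("degenerate standard curve: zero slope")
    return StandardCurve(slope=float(fit.slope), intercept=float(fit.intercept))


def nitrite_concentration(od: float, curve: StandardCurve) -> float:
    """Invert the standard curve: conc = (od - intercept) / slope, in uM.

    Negative inferred concentrations (od below the curve's intercept,
    i.e. below the zero standard) are clamped to 0 with a warning — the
    analyte is physically non-negative.
    """
    conc = (od - curve.intercept) / curve.slope
    if conc < 0:
        warnings.warn(
            f"negative inferred nitrite concentration {conc:.4g} uM clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return float(conc)


def unpaired_t_test(
    group_a_values: Sequence[float],
    group_b_values: Sequence[float],
    variant: Literal["student", "welch"] = "student",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-tailed unpaired t-test between two groups of measurements.

    ``student`` pools the variances (df = n_a + n_b - 2); ``welch`` drops
    the equal-variance assumption (Welch-Satterthwaite df). Two groups
    with zero variance and equal means give t = 0, p = 1 rather than an
    error. Each group needs n >= 2.
    """
    a = np.asarray(group_a_values, dtype=float)
    b = np.asarray(group_b_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = (
            a.size + b.size - 2
            if variant == "student"
            else float(a.size + b.size - 2)
        )
        return GroupComparison(group_a, group_b, 0.0, float(df), 1.0, "ns")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    p = float(res.pvalue)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=p,
        stars=significance_stars(p),
    )


def significance_stars(p_value: float) -> str:
    """Star annotation for a p-value; strict thresholds, most extreme wins.

    ``****`` p < 0.0001, ``***`` p < 0.001, ``**`` p < 0.01, ``*``
    p < 0.05, otherwise ``ns``.
    """
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p_value < cut:
            return stars
    return "ns"
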