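"""Reliability statistics for balanced repeated-digitization designs.

Each analyzed parameter (a landmark coordinate in the average scapula
frame, or an orientation angle) is a balanced grid of values indexed by
(scapula, observer, measure).  Its dispersion is decomposed under the
crossed random-effects main-effects model

    y_som = mu + a_s + b_o + c_m + e_som,

with a, b, c, e independent zero-mean effects for scapula, observer and
measure (repetition index) and residual.  Variance components are the
closed-form balanced ANOVA (method-of-moments) estimators with negative
estimates truncated to zero; the total variance is their sum.

Relative reliability is expressed as intraclass correlations

    ICC_intra = (s2_total - (s2_measure + s2_residual)) / s2_total
    ICC_inter = (s2_total - (s2_observer + s2_residual)) / s2_total

and absolute reliability as the standard error of measurement
SEM = sqrt(s2_total * (1 - ICC)), with 95% CI half-width 1.96 * SEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PARAMETER_IDS = (
    "AA_X", "AA_Y", "AA_Z",
    "IA_X", "IA_Y", "IA_Z",
    "TS_X", "TS_Y", "TS_Z",
    "e1", "e2", "e3",
)

_Z95 = 1.96


class ICCClass(str, Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class ParameterSeries:
    """Balanced (scapula, observer, measure) grid of one parameter's values."""

    parameter_id: str
    unit: str  # "mm" or "deg"
    values: np.ndarray  # shape (n_s, n_o, n_m)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"values must be 3D (scapula, observer, measure), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class MADSummary:
    mean: float
    std: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class VarianceComponents:
    """Truncated ANOVA variance components; total is their exact sum."""

    sigma2_scapula: float
    sigma2_observer: float
    sigma2_measure: float
    sigma2_residual: float
    raw: tuple[float, float, float, float] = field(default=None, compare=False)  # pre-truncation
    degenerate: bool = field(default=False, compare=False)

    @property
    def sigma2_total(self) -> float:
        return (
            self.sigma2_scapula
            + self.sigma2_observer
            + self.sigma2_measure
            + self.sigma2_residual
        )


@dataclass(frozen=True)
class ReliabilityRow:
    parameter_id: str
    unit: str
    mad: MADSummary
    components: VarianceComponents
    icc_intra: float  # NaN when undefined (zero total variance)
    icc_inter: float
    sem_intra: float
    sem_inter: float
    icc_intra_class: ICCClass
    icc_inter_class: ICCClass


def mean_absolute_deviation(series: ParameterSeries) -> MADSummary:
    """Average absolute distance of each value from its scapula mean.

    Deviations are pooled over all N = n_s * n_o * n_m observations; the CI
    is the normal approximation mean +/- 1.96 * std / sqrt(N).
    """
    v = series.values
    n_s, n_o, n_m = v.shape
    if n_o * n_m < 2:
        raise ValueError("need at least 2 observations per scapula for deviations")
    dev = np.abs(v - v.mean(axis=(1, 2), keepdims=True)).ravel()
    n = dev.size
    mean = float(dev.mean())
    std = float(dev.std(ddof=1)) if n > 1 else 0.0
    half = _Z95 * std / math.sqrt(n)
    return MADSummary(mean, std, mean - half, mean + half)


def estimate_variance_components(series: ParameterSeries) -> VarianceComponents:
    """Balanced crossed main-effects ANOVA (method-of-moments) estimates.

    Mean squares for the three main effects and the residual solve the
    expected-mean-squares equations in closed form:

        s2_res = MS_res
        s2_s   = (MS_s - MS_res) / (n_o * n_m)     (similarly for o, m)

    Negative estimates are truncated to zero before summation, so the
    reported total equals the reported component sum exactly.
    """
    v = series.values
    n_s, n_o, n_m = v.shape
    if n_s < 2 or n_o < 2 or n_m < 2:
        raise ValueError(f"need >= 2 levels of every factor, got {v.shape}")
    grand = v.mean()
    n = v.size
    ss_total = float(((v - grand) ** 2).sum())
    ss_s = n_o * n_m * float(((v.mean(axis=(1, 2)) - grand) ** 2).sum())
    ss_o = n_s * n_m * float(((v.mean(axis=(0, 2)) - grand) ** 2).sum())
    ss_m = n_s * n_o * float(((v.mean(axis=(0, 1)) - grand) ** 2).sum())
    ss_res = ss_total - ss_s - ss_o - ss_m
    df_res = n - n_s - n_o - n_m + 2
    ms_s = ss_s / (n_s - 1)
    ms_o = ss_o / (n_o - 1)
    ms_m = ss_m / (n_m - 1)
    ms_res = ss_res / df_res
    raw = (
        (ms_s - ms_res) / (n_o * n_m),
        (ms_o - ms_res) / (n_s * n_m),
        (ms_m - ms_res) / (n_s * n_o),
        ms_res,
    )
    truncated = tuple(max(0.0, x) for x in raw)
    # spread below 1e-9 of the value scale is numerical residue, not signal
    spread = float(v.max() - v.min())
    degenerate = spread <= 1e-9 * max(1.0, abs(grand))
    return VarianceComponents(*truncated, raw=raw, degenerate=degenerate)


def icc_intra(vc: VarianceComponents) -> float:
    """Repeatability across measures: share of variance not due to measure/residual."""
    if vc.sigma2_total <= 0:
        raise ZeroDivisionError("ICC undefined: zero total variance")
    return (vc.sigma2_total - (vc.sigma2_measure + vc.sigma2_residual)) / vc.sigma2_total


def icc_inter(vc: VarianceComponents) -> float:
    """Reproducibility across observers: share not due to observer/residual."""
    if vc.sigma2_total <= 0:
        raise ZeroDivisionError("ICC undefined: zero total variance")
    return (vc.sigma2_total - (vc.sigma2_observer + vc.sigma2_residual)) / vc.sigma2_total


def sem(sigma2_total: "VarianceComponents | float", icc: float) -> float:
    """Standard error of measurement: sqrt(s2_total * (1 - ICC)).

    Accepts the total variance directly or a :class:`VarianceComponents`.
    """
    if isinstance(sigma2_total, VarianceComponents):
        sigma2_total = sigma2_total.sigma2_total
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"ICC must be in [0, 1], got {icc}")
    return math.sqrt(sigma2_total * (1.0 - icc))


def reliability_ci(sem_value: float) -> float:
    """95% CI half-width: 1.96 * SEM."""
    if sem_value < 0:
        raise ValueError("SEM must be >= 0")
    return _Z95 * sem_value


def classify_icc(icc: float) -> ICCClass:
    """Koo-Li bands: <0.50 poor, [0.50, 0.75) moderate, [0.75, 0.90) good, >=0.90 excellent."""
    if math.isnan(icc):
        return ICCClass.UNDEFINED
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"ICC must be in [0, 1], got {icc}")
    if icc < 0.50:
        return ICCClass.POOR
    if icc < 0.75:
        return ICCClass.MODERATE
    if icc < 0.90:
        return ICCClass.GOOD
    return ICCClass.EXCELLENT


def effect_size_from_icc(icc: float, k: int) -> float:
    """Effect size d = (1 - ICC) / (1 + (k - 1) * ICC) for k raters."""
    if not 0.0 <= icc <= 1.0:
        raise ValueError(f"ICC must be in [0, 1], got {icc}")
    if k < 2:
        raise ValueError("k must be >= 2")
    return (1.0 - icc) / (1.0 + (k - 1) * icc)


def reliability_row(series: ParameterSeries) -> ReliabilityRow:
    """MAD, variance components, ICCs, SEMs and classes for one parameter."""
    mad = mean_absolute_deviation(series)
    vc = estimate_variance_components(series)
    if vc.sigma2_total <= 0 or vc.degenerate:
        nan = float("nan")
        return ReliabilityRow(
            series.parameter_id, series.unit, mad, vc,
            nan, nan, 0.0, 0.0, ICCClass.UNDEFINED, ICCClass.UNDEFINED,
        )
    intra = icc_intra(vc)
    inter = icc_inter(vc)
    return ReliabilityRow(
        series.parameter_id,
        series.unit,
        mad,
        vc,
        intra,
        inter,
        sem(vc, intra),
        sem(vc, inter),
        classify_icc(intra),
        classify_icc(inter),
    )


def reliability_table(series_set: Iterable[ParameterSeries]) -> list[ReliabilityRow]:
    """One reliability row per parameter; all series must share one grid."""
    series_set = list(series_set)
    shapes = {s.shape for s in series_set}
    if len(shapes) > 1:
        raise ValueError(f"series are not on a common balanced grid: {shapes}")
    return [reliability_row(s) for s in series_set]


def table_to_frame(rows: Sequence[ReliabilityRow], rounded: bool = False) -> pd.DataFrame:
    """Tabulate reliability rows; display rounding is 1 dp mm/deg, 2 dp ICC."""
    data = []
    for r in rows:
        rec = {
            "parameter": r.parameter_id,
            "unit": r.unit,
            "mad_mean": r.mad.mean,
            "mad_std": r.mad.std,
            "mad_ci_low": r.mad.ci_low,
            "mad_ci_high": r.mad.ci_high,
            "icc_intra": r.icc_intra,
            "sem_intra": r.sem_intra,
            "icc_inter": r.icc_inter,
            "sem_inter": r.sem_inter,
            "icc_intra_class": r.icc_intra_class.value,
            "icc_inter_class": r.icc_inter_class.value,
        }
        if rounded:
            for key in ("mad_mean", "mad_std", "mad_ci_low", "mad_ci_high", "sem_intra", "sem_inter"):
                rec[key] = round(rec[key], 1)
            for key in ("icc_intra", "icc_inter"):
                rec[key] = round(rec[key], 2)
        data.append(rec)
    return pd.DataFrame(data)
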