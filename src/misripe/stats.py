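"""Cohort statistics: correlation, variance decomposition, outliers.

A ripening study yields a balanced samples × days matrix of a summary
statistic (here usually Py).  Three questions recur: does the statistic
track ripening day (Pearson correlation with a two-sided t-test p-value);
how much of the total variability is between-fruit individuality rather
than ripening or noise (two-way additive sum-of-squares decomposition,
share ρ = SS_sample / SS_total); and which fruit deviate from the cohort on
a given day (Tukey 1.5·IQR fences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dispersion import PropertySpectrum, compute_py


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")
        if self.n < 3:
            raise ValueError("need at least 3 observations")


@dataclass(frozen=True)
class VarianceDecomposition:
    ss_sample: float
    ss_day: float
    ss_residual: float
    ss_total: float

    @property
    def rho(self) -> float:
        """Share of total variability due to between-sample differences."""
        return self.ss_sample / self.ss_total if self.ss_total > 0 else 0.0


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson r with a two-sided p-value (t transform, n−2 d.o.f.)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             n=len(x))


def variance_decomposition(py_matrix: np.ndarray) -> VarianceDecomposition:
    """Two-way additive SS partition of a balanced samples × days matrix.

    SS_sample = days·Σᵢ(mᵢ − m)², SS_day = samples·Σⱼ(mⱼ − m)², and the
    interaction/noise remainder is SS_residual; the three sum exactly to the
    total sum of squared deviations from the grand mean.
    """
    m = np.asarray(py_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D samples × days matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be complete (no missing cells)")
    n_s, n_d = m.shape
    grand = m.mean()
    sample_means = m.mean(axis=1)
    day_means = m.mean(axis=0)
    ss_sample = n_d * float(np.sum((sample_means - grand) ** 2))
    ss_day = n_s * float(np.sum((day_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_residual = ss_total - ss_sample - ss_day
    return VarianceDecomposition(ss_sample, ss_day, max(ss_residual, 0.0),
                                 ss_total)


@dataclass(frozen=True)
class OutlierResult:
    flags: np.ndarray
    lower_fence: float
    upper_fence: float
    q1: float
    q3: float


def iqr_outliers(values: Sequence[float]) -> OutlierResult:
    """Tukey fences: flag points outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation between order statistics.  For
    constant data the fences collapse onto the constant, so any deviating
    value is flagged.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return OutlierResult(flags=(v < lo) | (v > hi), lower_fence=float(lo),
                         upper_fence=float(hi), q1=float(q1), q3=float(q3))


def daily_summary(
    specs: Sequence[PropertySpectrum],
    f_low: float | None = None,
    f_high: float | None = None,
) -> pd.DataFrame:
    """Per-day cohort summary of spectra and Py.

    Reports both the mean of per-sample Py values and the Py of the day's
    mean conductivity spectrum — they differ whenever the high-frequency
    endpoint varies across samples — plus boxplot statistics (median,
    quartiles, whisker fences, outlier count).
    """
    if not specs:
        raise ValueError("no spectra supplied")
    kw = {}
    if f_low is not None:
        kw["f_low"] = f_low
    if f_high is not None:
        kw["f_high"] = f_high
    rows = []
    by_day: dict[int, list[PropertySpectrum]] = {}
    for sp in specs:
        by_day.setdefault(sp.day, []).append(sp)
    for day in sorted(by_day):
        group = by_day[day]
        pys = np.array([compute_py(sp, **kw).py for sp in group])
        mean_spec = PropertySpectrum(
            sample_id="__mean__", day=day, freqs=group[0].freqs,
            sigma=np.mean([sp.sigma for sp in group], axis=0),
            eps_r=np.mean([sp.eps_r for sp in group], axis=0),
        )
        row = {
            "day": day,
            "n": len(group),
            "py_mean": float(pys.mean()),
            "py_median": float(np.median(pys)),
            "py_of_mean_spectrum": compute_py(mean_spec, **kw).py,
        }
        if len(pys) >= 4:
            out = iqr_outliers(pys)
            row.update(q1=out.q1, q3=out.q3, lower_fence=out.lower_fence,
                       upper_fence=out.upper_fence,
                       n_outliers=int(out.flags.sum()))
        else:
            row.update(q1=np.nan, q3=np.nan, lower_fence=np.nan,
                       upper_fence=np.nan, n_outliers=0)
        rows.append(row)
    return pd.DataFrame(rows)
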