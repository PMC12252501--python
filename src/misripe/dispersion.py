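"""Cole–Cole dispersion model and conductivity-spectrum metrics.

Biological tissue in the 100 kHz – 10 MHz band exhibits β-dispersion:
interfacial (cell-membrane) polarisation makes the relative permittivity
fall and the conductivity rise with frequency.  The empirical Cole–Cole
relaxation

.. math::

    \\varepsilon^*(\\omega) = \\varepsilon_\\infty +
        \\frac{\\varepsilon_s - \\varepsilon_\\infty}
             {1 + (j\\omega\\tau)^{1-\\alpha}}

broadens the ideal Debye relaxation by the exponent α ∈ [0, 1).  The
relaxation term here is a *relative* permittivity; an explicit DC ionic
conduction term ``sigma_dc`` is carried separately so the derived
conductivity is

.. math::

    \\sigma(\\omega) = \\sigma_{dc}
        + \\omega \\varepsilon_0 \\,(-\\mathrm{Im}\\,\\varepsilon^*(\\omega)),

which reproduces the nonzero low-frequency conductivity observed in real
tissue.  The flatness of a measured conductivity spectrum is summarised by
the normalised gradient

.. math::

    P_y = \\frac{\\hat\\sigma(f_{high}) - \\hat\\sigma(f_{low})}
               {\\hat\\sigma(f_{high})},

a dimensionless statistic that cancels any multiplicative geometry/size
factor and so compares across samples of different mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .physics import EPS_0

DEFAULT_F_LOW: float = 100e3
DEFAULT_F_HIGH: float = 3e6


@dataclass(frozen=True)
class ColeColeParams:
    """Single-relaxation Cole–Cole parameters plus DC conduction.

    Attributes
    ----------
    eps_s : static (low-frequency) relative permittivity.
    eps_inf : high-frequency relative permittivity.
    tau : relaxation time, s.
    alpha_cc : broadening exponent in [0, 1); 0 is Debye.
    sigma_dc : low-frequency ionic conductivity, S/m.
    """

    eps_s: float
    eps_inf: float
    tau: float
    alpha_cc: float
    sigma_dc: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps_s > self.eps_inf:
            raise ValueError("eps_s must exceed eps_inf")
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.alpha_cc < 1:
            raise ValueError("alpha_cc must lie in [0, 1)")
        if self.sigma_dc < 0:
            raise ValueError("sigma_dc must be non-negative")


@dataclass
class PropertySpectrum:
    """σ(ω) and εr(ω) for one sample on one day."""

    sample_id: str
    day: int
    freqs: np.ndarray
    sigma: np.ndarray
    eps_r: np.ndarray
    quality: np.ndarray | None = None  # True where inversion was non-physical

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.eps_r = np.asarray(self.eps_r, dtype=float)
        if not (len(self.freqs) == len(self.sigma) == len(self.eps_r)):
            raise ValueError("freqs, sigma and eps_r must have equal length")
        if self.quality is None:
            self.quality = np.zeros(len(self.freqs), dtype=bool)


@dataclass(frozen=True)
class PyValue:
    sample_id: str
    day: int
    py: float


def cole_cole_eval(params: ColeColeParams, freqs: Sequence[float]) -> np.ndarray:
    """Complex relative permittivity ε*(ω) on a frequency grid."""
    f = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * f
    relax = (params.eps_s - params.eps_inf) / (
        1.0 + (1j * omega * params.tau) ** (1.0 - params.alpha_cc)
    )
    return params.eps_inf + relax


def cole_cole_spectrum(
    params: ColeColeParams,
    freqs: Sequence[float],
    sample_id: str = "",
    day: int = 0,
) -> PropertySpectrum:
    """Evaluate the tissue model as a (σ, εr) property spectrum.

    σ(ω) = sigma_dc + ω·ε0·(−Im ε*), εr(ω) = Re ε*.
    """
    f = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * f
    eps = cole_cole_eval(params, f)
    sigma = params.sigma_dc + omega * EPS_0 * (-eps.imag)
    return PropertySpectrum(sample_id=sample_id, day=day, freqs=f,
                            sigma=sigma, eps_r=eps.real.copy())


def compute_py(
    spec: PropertySpectrum,
    f_low: float = DEFAULT_F_LOW,
    f_high: float = DEFAULT_F_HIGH,
) -> PyValue:
    """Normalised conductivity gradient Py = (σ(f_high) − σ(f_low))/σ(f_high).

    Both endpoint frequencies must be present on the grid (no interpolation);
    a non-positive high-frequency conductivity leaves Py undefined.
    """
    i_low = _grid_index(spec.freqs, f_low)
    i_high = _grid_index(spec.freqs, f_high)
    s_high = spec.sigma[i_high]
    if s_high <= 0:
        raise ValueError(
            f"Py undefined: sigma({f_high:g} Hz) = {s_high:g} is not positive"
        )
    return PyValue(spec.sample_id, spec.day,
                   float((s_high - spec.sigma[i_low]) / s_high))


def _grid_index(freqs: np.ndarray, f: float) -> int:
    idx = np.flatnonzero(np.isclose(freqs, f, rtol=1e-9))
    if idx.size == 0:
        raise ValueError(f"frequency {f:g} Hz not on the grid")
    return int(idx[0])


def cole_trajectory(specs: Sequence[PropertySpectrum]) -> np.ndarray:
    """Day-ordered Cole-plane locus of the complex permittivity.

    Returns a structured array of (day, frequency_hz, re, im) rows where
    ``re`` is εr(ω) and ``im`` is the loss part σ(ω)/(ωε0) plotted upward,
    so a ripening fruit traces the familiar upper-left drift.
    """
    if len(specs) == 0:
        raise ValueError("need at least one spectrum")
    rows = []
    for spec in sorted(specs, key=lambda s: s.day):
        omega = 2.0 * np.pi * spec.freqs
        loss = spec.sigma / (omega * EPS_0)
        for f, re, im in zip(spec.freqs, spec.eps_r, loss):
            rows.append((spec.day, f, re, im))
    return np.array(
        rows,
        dtype=[("day", int), ("frequency_hz", float), ("re", float), ("im", float)],
    )


@dataclass(frozen=True)
class StageSegmentation:
    """Two change points splitting a Py series into pre-ripe / ripe / overripe."""

    c1: int
    c2: int
    sse: float
    slopes: tuple[float, float, float]
    degenerate: bool = False


def segment_ripening_stages(
    py_series: Sequence[float],
    days: Sequence[int] | None = None,
    min_seg: int = 2,
    degenerate_rtol: float = 1e-3,
) -> StageSegmentation:
    """Fit a continuous three-segment piecewise-linear model to a Py series.

    Breakpoints are searched on the integer-day grid (ties broken toward the
    earlier pair), and each segment must span at least ``min_seg`` days.  A
    series that a single straight line already fits (SSE within
    ``degenerate_rtol`` of the best three-segment fit, relative to the series
    variance) is flagged degenerate: its breakpoints are not meaningful.
    """
    y = np.asarray(py_series, dtype=float)
    if days is None:
        d = np.arange(len(y), dtype=float)
    else:
        d = np.asarray(days, dtype=float)
    if len(y) < 6:
        raise ValueError("need at least 6 days to segment three stages")

    def fit_sse(c1: float, c2: float) -> tuple[float, np.ndarray]:
        # continuous piecewise-linear basis: 1, d, hinge(c1), hinge(c2)
        X = np.column_stack([
            np.ones_like(d), d,
            np.maximum(d - c1, 0.0), np.maximum(d - c2, 0.0),
        ])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), beta

    best: tuple[float, int, int, np.ndarray] | None = None
    lo, hi = int(d[0]), int(d[-1])
    for c1 in range(lo + min_seg, hi - 2 * min_seg + 1):
        for c2 in range(c1 + min_seg, hi - min_seg + 1):
            sse, beta = fit_sse(c1, c2)
            if best is None or sse < best[0] - 1e-15:
                best = (sse, c1, c2, beta)
    assert best is not None
    sse, c1, c2, beta = best
    slopes = (float(beta[1]), float(beta[1] + beta[2]),
              float(beta[1] + beta[2] + beta[3]))

    # compare against a single straight line
    X1 = np.column_stack([np.ones_like(d), d])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ b1
    sse_line = float(r1 @ r1)
    scale = float(np.var(y) * len(y)) or 1.0
    degenerate = (sse_line - sse) / scale < degenerate_rtol
    return StageSegmentation(c1, c2, sse, slopes, degenerate)
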