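"""Equivalent-circuit models of plant tissue and their fitting.

Plant tissue in the β-dispersion band is classically modelled by an
extracellular resistance R₂ in parallel with an intracellular branch: R₁ in
series with the membrane capacitance.  Replacing the ideal capacitor with a
constant phase element (CPE),

    Z_CPE = 1 / (Q (jω)^α),       0 ≤ α ≤ 1,

captures the distributed, imperfect capacitance of real membranes (α = 1 is
a pure capacitor, α = 0 a resistor).  Four topologies are provided:

* ``A`` — Hayden:          Y = 1/R₂ + 1/(R₁ + 1/(jωC))
* ``B`` — Modified Hayden: Y = 1/R₂ + 1/(R₁ + Z_CPE)
* ``C`` — standard Cole circuit: Z = R∞ + ΔR/(1 + ΔR·Q(jω)^α), Y = 1/Z
* ``D`` — single Cole impedance function:
          Z = R∞ + (R₀ − R∞)/(1 + (jωτ)^{1−α}), Y = 1/Z

The circuit admittance maps to an effective complex conductivity through a
cell constant, σ*(ω) = κ·Y(ω); only its real part is fitted to the measured
conductivity spectrum (the permittivity channel is too noisy at low
frequency to constrain the fit).  Fitting uses Differential Evolution with
an RMSE cost normalised by the RMS of the measured values, so the reported
``rmse_pct`` is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .dispersion import PropertySpectrum

MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "A": ("r1", "r2", "c"),
    "B": ("r1", "r2", "q", "alpha_cpe"),
    "C": ("r_inf", "r0", "q", "alpha_cpe"),
    "D": ("r_inf", "r0", "tau", "alpha_cc"),
}


@dataclass(frozen=True)
class CircuitParams:
    """Parameters of one equivalent-circuit model; only the fields of the
    selected model are active (see :data:`MODEL_PARAM_NAMES`)."""

    model_id: str
    r1: float | None = None
    r2: float | None = None
    c: float | None = None
    q: float | None = None
    alpha_cpe: float | None = None
    r_inf: float | None = None
    r0: float | None = None
    tau: float | None = None
    alpha_cc: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model {self.model_id!r}")
        for name in MODEL_PARAM_NAMES[self.model_id]:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"model {self.model_id} requires parameter {name}")
            if name.startswith(("r", "c", "q", "tau")) and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        a = self.alpha_cpe if self.model_id in ("B", "C") else self.alpha_cc
        if self.model_id != "A" and not 0 <= a <= 1:
            raise ValueError("CPE / Cole exponent must lie in [0, 1]")

    def values(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in MODEL_PARAM_NAMES[self.model_id])

    @classmethod
    def from_values(cls, model_id: str, values: Sequence[float]) -> "CircuitParams":
        names = MODEL_PARAM_NAMES[model_id]
        if len(values) != len(names):
            raise ValueError(f"model {model_id} takes {len(names)} parameters")
        return cls(model_id=model_id, **dict(zip(names, values)))


@dataclass(frozen=True)
class CircuitFit:
    params: CircuitParams
    rmse_pct: float
    converged: bool
    n_evals: int
    seed: int

    def __post_init__(self) -> None:
        if self.rmse_pct < 0:
            raise ValueError("rmse_pct must be non-negative")


def cpe_impedance(q: float, alpha_cpe: float, freq) -> complex | np.ndarray:
    """Constant-phase-element impedance 1/(Q(jω)^α), principal branch.

    Phase is −α·π/2 at every frequency, hence the element's name.
    """
    if not q > 0:
        raise ValueError(f"CPE magnitude q must be positive, got {q}")
    omega = 2.0 * np.pi * np.asarray(freq, dtype=float)
    return 1.0 / (q * (1j * omega) ** alpha_cpe)


def circuit_admittance(params: CircuitParams, freqs) -> np.ndarray:
    """Complex admittance Y(ω) of the selected topology, siemens."""
    omega = 2.0 * np.pi * np.asarray(freqs, dtype=float)
    m = params.model_id
    if m == "A":
        z_branch = params.r1 + 1.0 / (1j * omega * params.c)
        return 1.0 / params.r2 + 1.0 / z_branch
    if m == "B":
        z_branch = params.r1 + cpe_impedance(params.q, params.alpha_cpe, freqs)
        return 1.0 / params.r2 + 1.0 / z_branch
    if m == "C":
        delta_r = params.r0 - params.r_inf
        if delta_r <= 0:
            raise ValueError("model C requires r0 > r_inf")
        z_par = delta_r / (1.0 + delta_r * params.q * (1j * omega) ** params.alpha_cpe)
        return 1.0 / (params.r_inf + z_par)
    if m == "D":
        if params.r0 <= params.r_inf:
            raise ValueError("model D requires r0 > r_inf")
        z = params.r_inf + (params.r0 - params.r_inf) / (
            1.0 + (1j * omega * params.tau) ** (1.0 - params.alpha_cc)
        )
        return 1.0 / z
    raise ValueError(f"unknown model {m!r}")


def admittance_to_conductivity(y, cell_constant: float = 1.0) -> np.ndarray:
    """Map admittance to effective complex conductivity, σ* = κ·Y (S/m)."""
    if not cell_constant > 0:
        raise ValueError("cell constant must be positive")
    return np.asarray(y, dtype=complex) * cell_constant


def model_conductivity(params: CircuitParams, freqs,
                       cell_constant: float = 1.0) -> np.ndarray:
    """Real conductivity component predicted by the circuit."""
    return admittance_to_conductivity(
        circuit_admittance(params, freqs), cell_constant
    ).real


def rmse_percent(predicted: np.ndarray, measured: np.ndarray) -> float:
    """RMSE normalised by the RMS of the measured values, in percent."""
    measured = np.asarray(measured, dtype=float)
    rms = np.sqrt(np.mean(measured**2))
    if rms == 0:
        raise ValueError("measured spectrum has zero RMS")
    return float(100.0 * np.sqrt(np.mean((predicted - measured) ** 2)) / rms)


def default_bounds(model_id: str, spec: PropertySpectrum,
                   cell_constant: float = 1.0) -> list[tuple[float, float]]:
    """Data-scaled parameter bounds: resistances span [1e-3, 1e3]× the scale
    implied by the measured conductivity level; exponents span [0, 1]."""
    sigma_scale = float(np.median(np.abs(spec.sigma))) or 1.0
    r_scale = cell_constant / sigma_scale
    omega_mid = 2.0 * np.pi * float(np.sqrt(spec.freqs[0] * spec.freqs[-1]))
    r_b = (1e-3 * r_scale, 1e3 * r_scale)
    c_b = (1e-3 / (r_scale * omega_mid), 1e3 / (r_scale * omega_mid))
    q_b = (1e-4 / (r_scale * omega_mid), 1e4 / (r_scale * omega_mid))
    tau_b = (1e-3 / omega_mid, 1e3 / omega_mid)
    table = {
        "A": [r_b, r_b, c_b],
        "B": [r_b, r_b, q_b, (0.0, 1.0)],
        "C": [r_b, r_b, q_b, (0.0, 1.0)],
        "D": [r_b, r_b, tau_b, (0.0, 1.0)],
    }
    return table[model_id]


_DE_DEFAULTS = dict(strategy="rand1bin", mutation=0.8, recombination=0.9,
                    tol=1e-8, maxiter=2000, polish=True, init="sobol")


def fit_circuit(
    spec: PropertySpectrum,
    model_id: str = "B",
    bounds: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
    cell_constant: float = 1.0,
    de_config: dict | None = None,
) -> CircuitFit:
    """Fit a circuit model to the conductivity component by Differential
    Evolution.

    The cost is the scale-free RMSE (percent of the measured RMS) between
    Re σ*(ω) of the circuit and the measured σ(ω).  Deterministic under
    ``seed``.  Needs at least 5 frequencies for the 3–4 parameter models.
    """
    if len(spec.freqs) < 5:
        raise ValueError("need at least 5 frequencies to fit 4-5 parameters")
    if not np.all(np.isfinite(spec.sigma)):
        raise ValueError("spectrum contains non-finite conductivity values")
    if bounds is None:
        bounds = default_bounds(model_id, spec, cell_constant)
    if len(bounds) == 0:
        raise ValueError("empty parameter bounds")
    names = MODEL_PARAM_NAMES[model_id]
    if len(bounds) != len(names):
        raise ValueError(f"model {model_id} takes {len(names)} parameters")
    measured = spec.sigma
    freqs = spec.freqs
    # DE explores in log space for the positive scale parameters so the
    # [1e-3, 1e3]x bounds are searched evenly per decade
    log_mask = np.array([not n.startswith("alpha") for n in names])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    tlo = np.where(log_mask, np.log(np.maximum(lo, 1e-300)), lo)
    thi = np.where(log_mask, np.log(hi), hi)

    def unpack(x: np.ndarray) -> np.ndarray:
        return np.where(log_mask, np.exp(x), x)

    def cost(x: np.ndarray) -> float:
        vals = unpack(x)
        try:
            p = CircuitParams.from_values(model_id, vals)
            pred = model_conductivity(p, freqs, cell_constant)
        except ValueError:
            return 1e12
        if not np.all(np.isfinite(pred)):
            return 1e12
        return rmse_percent(pred, measured)

    cfg = dict(_DE_DEFAULTS)
    if de_config:
        cfg.update(de_config)
    result = differential_evolution(
        cost, list(zip(tlo, thi)), seed=seed,
        popsize=15, **cfg,
    )
    params = CircuitParams.from_values(model_id, unpack(result.x))
    return CircuitFit(params=params, rmse_pct=float(result.fun),
                      converged=bool(result.success), n_evals=int(result.nfev),
                      seed=seed)


def normalize_fit_series(fits: Sequence[CircuitFit]) -> dict[str, np.ndarray]:
    """Divide each fitted parameter's day series by its across-day mean.

    Mean-normalisation puts parameters of very different magnitudes on one
    axis so ripening trends can be compared (for example an extracellular
    resistance falling from 1.6× to 0.3× of its mean).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 days of fits")
    model = fits[0].params.model_id
    if any(f.params.model_id != model for f in fits):
        raise ValueError("all fits must use one model")
    out: dict[str, np.ndarray] = {}
    for name in MODEL_PARAM_NAMES[model]:
        series = np.array([getattr(f.params, name) for f in fits], dtype=float)
        mean = series.mean()
        if mean == 0:
            raise ValueError(f"parameter {name} has zero mean; cannot normalise")
        out[name] = series / mean
    return out
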