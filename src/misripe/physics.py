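"""Forward model for a conductive, permittive sphere in a uniform AC field.

A non-magnetic sphere of radius ``a`` placed in a uniform primary magnetic
field :math:`B_1 \\cos\\omega t` re-emits a secondary field :math:`B_2`
through induced eddy currents.  Outside the sphere the axial secondary field
at a point at distance ``r`` from the sphere centre (axial component ``z``)
is

.. math::

    \\frac{B_2}{B_1} = -\\frac{j_2(ka)}{j_0(ka)}
                       \\frac{a^3 (r^2 - 3z^2)}{2 r^5},

where :math:`j_n` are spherical Bessel functions of the first kind and the
complex wavenumber satisfies
:math:`k^2 = \\mu_0 \\varepsilon_0 \\varepsilon_r \\omega^2
- j\\mu_0\\sigma\\omega`.

In the low-induction-number regime relevant to fruit tissue
(:math:`|ka| \\ll 1`) the Bessel ratio reduces to :math:`(ka)^2/15`, giving
the first-order model

.. math::

    \\frac{B_2}{B_1} = P\\,\\mu_0\\omega
        (\\varepsilon_0\\varepsilon_r\\omega - j\\sigma),
    \\qquad P = \\frac{a^5 (3z^2 - r^2)}{30 r^5}.

``P`` lumps all geometry; a measurement system determines it by calibration
against a reference object of known conductivity.  The skin-effect regime
(|ka| of order 1 and above) is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.special import spherical_jn

MU_0: float = 4.0e-7 * np.pi
"""Vacuum permeability, H/m."""

EPS_0: float = 8.8541878128e-12
"""Vacuum permittivity, F/m."""

Mode = Literal["exact", "first_order"]


@dataclass(frozen=True)
class SphereGeometry:
    """Sphere radius and observation point, SI metres.

    ``r`` is the total distance of the observation point from the sphere
    centre and ``z`` its axial component, so the on-axis case is ``z == r``
    and the equatorial plane is ``z == 0``.
    """

    a: float
    r: float
    z: float

    def __post_init__(self) -> None:
        if not self.a >= 0:
            raise ValueError(f"sphere radius must be non-negative, got {self.a}")
        if not self.r > 0:
            raise ValueError(f"observation distance must be positive, got {self.r}")
        if self.r < self.a:
            raise ValueError("observation point must lie outside the sphere (r >= a)")
        if abs(self.z) > self.r * (1 + 1e-12):
            raise ValueError("|z| must not exceed r (z is the axial component of r)")


@dataclass(frozen=True)
class MaterialProperties:
    """Electrical conductivity (S/m) and relative permittivity of the sphere."""

    sigma: float
    eps_r: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"conductivity must be non-negative, got {self.sigma}")
        if self.eps_r < 1:
            raise ValueError(f"relative permittivity must be >= 1, got {self.eps_r}")


def wavenumber_squared(freq: float, props: MaterialProperties) -> complex:
    """Complex squared wavenumber k² = μ0ε0εrω² − jμ0σω, 1/m².

    Parameters
    ----------
    freq : excitation frequency, Hz (must be positive).
    props : material properties of the sphere.
    """
    if not freq > 0:
        raise ValueError(f"frequency must be positive, got {freq}")
    omega = 2.0 * np.pi * freq
    return MU_0 * EPS_0 * props.eps_r * omega**2 - 1j * MU_0 * props.sigma * omega


def _bessel_ratio_series(ka_sq: complex, terms: int = 6) -> complex:
    # j2(x)/j0(x) as a ratio of the two even power series; both series are
    # functions of x^2 only, so no branch cut of sqrt(k^2) is involved.
    # j0(x) = sum (-u)^k / ((2k+1)!/(2^k k!))  with u = x^2/2 ... computed
    # via the standard double-factorial form jn(x) = x^n sum (-x^2/2)^k /
    # (k! (2n+2k+1)!!).
    u = -ka_sq / 2.0
    num = 0.0 + 0.0j  # j2(x) / x^2
    den = 0.0 + 0.0j  # j0(x)
    fact = 1.0
    for k in range(terms):
        if k:
            fact *= k
        num += u**k / (fact * _double_factorial(2 * k + 5))
        den += u**k / (fact * _double_factorial(2 * k + 1))
    return ka_sq * num / den


def _double_factorial(n: int) -> float:
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


def bessel_ratio(ka: complex, mode: Literal["exact", "approx"] = "exact") -> complex:
    """Ratio j₂(ka)/j₀(ka) of spherical Bessel functions.

    ``approx`` returns the leading small-argument term (ka)²/15.  ``exact``
    uses the library spherical Bessel functions for a real argument and a
    six-term power-series ratio for complex argument; the series is accurate
    to better than 1e-12 for |ka| < 1, which covers the whole
    low-induction-number regime this package addresses.
    """
    ka = complex(ka)
    if mode == "approx":
        return ka * ka / 15.0
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    if ka.imag == 0.0:
        x = ka.real
        j0 = spherical_jn(0, x)
        if abs(j0) < 1e-12:
            raise ZeroDivisionError(f"j0({x}) is (numerically) zero")
        return complex(spherical_jn(2, x) / j0)
    return _bessel_ratio_series(ka * ka)


def geometric_factor(geom: SphereGeometry) -> float:
    """Lumped geometric factor P = a⁵(3z² − r²)/(30 r⁵), dimensionless.

    Homogeneous of degree zero: scaling (a, r, z) together leaves P fixed.
    """
    if geom.r == 0:
        raise ZeroDivisionError("observation distance r must be nonzero")
    return geom.a**5 * (3.0 * geom.z**2 - geom.r**2) / (30.0 * geom.r**5)


def field_ratio(
    geom: SphereGeometry,
    props: MaterialProperties,
    freq: float,
    mode: Mode = "exact",
) -> complex:
    """Secondary-to-primary field ratio B₂/B₁ for the sphere.

    ``exact`` composes the full Bessel ratio with the dipole positional
    factor; ``first_order`` is the small-ka limit P·μ0ω(ε0εrω − jσ).  The
    two agree to O((ka)⁴) as ka → 0.
    """
    k2 = wavenumber_squared(freq, props)
    if mode == "first_order":
        omega = 2.0 * np.pi * freq
        return geometric_factor(geom) * MU_0 * omega * (
            EPS_0 * props.eps_r * omega - 1j * props.sigma
        )
    if mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    ka = np.sqrt(k2 + 0.0j) * geom.a  # principal branch; only ka^2 matters
    pos = geom.a**3 * (geom.r**2 - 3.0 * geom.z**2) / (2.0 * geom.r**5)
    return -bessel_ratio(ka, "exact") * pos


def lumped_field_ratio(
    props: MaterialProperties, freq: float, p_factor: float = 1.0
) -> complex:
    """First-order ratio with the geometry lumped into ``p_factor``.

    This is the form a calibrated instrument reports: with P normalised to 1
    by magnitude calibration, inversion for (σ, εr) is a two-line algebraic
    step (see :mod:`misripe.calibration`).
    """
    omega = 2.0 * np.pi * freq
    if not freq > 0:
        raise ValueError(f"frequency must be positive, got {freq}")
    return p_factor * MU_0 * omega * (EPS_0 * props.eps_r * omega - 1j * props.sigma)
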