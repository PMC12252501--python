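"""Calibration of raw scans and inversion to property spectra.

A raw receive voltage mixes the wanted secondary-field signal with direct
transmit–receive coupling, amplifier phase shifts and an unknown overall
gain.  Three reference scans remove these in sequence:

1. **Background subtraction** — an empty-region scan captures the residual
   direct coupling; it is subtracted complex-wise per frequency.
2. **Phase calibration** — a non-conductive, magnetically permeable ferrite
   rod has a purely real, positive intrinsic response, so the phase of its
   background-subtracted scan is pure system phase; every scan is rotated
   by its negative.
3. **Magnitude calibration** — a saline reference of known conductivity
   pins the absolute scale: per frequency the measured saline response is
   matched to the first-order model ratio P·μ0ω(ε0εrω − jσ) with P = 1,
   which absorbs the geometric factor into the calibration.

After all three steps a scan is in units of B₂/B₁ with P ≡ 1 and inverts
algebraically:

    σ(ω)  = −Im S(ω) / (μ0 ω)
    εr(ω) =  Re S(ω) / (μ0 ε0 ω²)

Noise can push either quantity negative at low frequency; such points are
kept (so downstream statistics see unbiased noise) and marked with a
quality flag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dispersion import PropertySpectrum
from .physics import EPS_0, MU_0, MaterialProperties, lumped_field_ratio
from .synthetic import RawScan


@dataclass(frozen=True)
class CalibrationBundle:
    """The three reference scans plus the saline's known conductivity."""

    background: RawScan
    ferrite: RawScan
    saline: RawScan
    saline_sigma: float
    saline_eps_r: float = 80.0

    def __post_init__(self) -> None:
        if not self.saline_sigma > 0:
            raise ValueError("saline conductivity must be positive")
        for other in (self.ferrite, self.saline):
            if not np.allclose(other.freqs, self.background.freqs):
                raise ValueError("calibration scans must share one frequency grid")


def _check_grid(scan: RawScan, bundle: CalibrationBundle) -> None:
    if not np.allclose(scan.freqs, bundle.background.freqs):
        raise ValueError("scan frequency grid does not match the bundle")


def subtract_background(scan: RawScan, bundle: CalibrationBundle) -> RawScan:
    """Remove the direct-coupling offset measured in the empty region."""
    _check_grid(scan, bundle)
    return replace(scan, voltages=scan.voltages - bundle.background.voltages)


def phase_rotations(bundle: CalibrationBundle) -> np.ndarray:
    """Per-frequency system phase, from the ferrite reference (radians)."""
    ferr = bundle.ferrite.voltages - bundle.background.voltages
    if np.any(np.abs(ferr) == 0):
        raise ValueError("zero ferrite response: phase calibration failed")
    return np.angle(ferr)


def phase_calibrate(scan: RawScan, bundle: CalibrationBundle) -> RawScan:
    """Rotate each frequency so the ferrite reference becomes real positive.

    The input is expected to be background-subtracted already; the rotation
    angle per frequency is −arg(ferrite − background).
    """
    _check_grid(scan, bundle)
    rot = np.exp(-1j * phase_rotations(bundle))
    return replace(scan, voltages=scan.voltages * rot)


def magnitude_calibrate(scan: RawScan, bundle: CalibrationBundle) -> RawScan:
    """Scale a (background-subtracted, phase-calibrated) scan to B₂/B₁ units.

    The complex per-frequency factor c(ω) = model(saline)/measured(saline)
    absorbs the gain magnitude, the lumped geometric factor and any residual
    phase, making the first-order inversion directly applicable.
    """
    _check_grid(scan, bundle)
    saline_meas = phase_calibrate(
        subtract_background(bundle.saline, bundle), bundle
    ).voltages
    if np.any(np.abs(saline_meas) == 0):
        raise ValueError("zero saline response: magnitude calibration failed")
    props = MaterialProperties(bundle.saline_sigma, bundle.saline_eps_r)
    expected = np.array([
        lumped_field_ratio(props, f) for f in bundle.saline.freqs
    ])
    return replace(scan, voltages=scan.voltages * expected / saline_meas)


def calibrate_scan(scan: RawScan, bundle: CalibrationBundle) -> RawScan:
    """Full chain: background subtraction, phase, then magnitude calibration."""
    out = subtract_background(scan, bundle)
    out = phase_calibrate(out, bundle)
    return magnitude_calibrate(out, bundle)


def invert_to_properties(scan: RawScan, sample_id: str | None = None,
                         day: int | None = None) -> PropertySpectrum:
    """Invert a calibrated B₂/B₁ scan to σ(ω) and εr(ω).

    Non-physical outputs (σ < 0 or εr < 1, possible under noise at low
    frequency) are retained but flagged.
    """
    omega = 2.0 * np.pi * scan.freqs
    s = scan.voltages
    sigma = -s.imag / (MU_0 * omega)
    eps_r = s.real / (MU_0 * EPS_0 * omega**2)
    flag = (sigma < 0) | (eps_r < 1)
    return PropertySpectrum(
        sample_id=sample_id if sample_id is not None else (scan.sample_id or ""),
        day=day if day is not None else scan.day,
        freqs=scan.freqs.copy(), sigma=sigma, eps_r=eps_r, quality=flag,
    )


def process_scan_set(
    scans: Sequence[RawScan],
    saline_sigma: float,
    saline_eps_r: float = 80.0,
) -> list[PropertySpectrum]:
    """Calibrate and invert every sample scan of one session.

    The ferrite and saline scans of the session form the bundle; each sample
    scan is paired with the nearest *preceding* background scan (background
    re-measurement mid-session is thereby honoured without interpolation).
    """
    backgrounds = sorted(
        (s for s in scans if s.object_kind == "background"),
        key=lambda s: s.scan_index,
    )
    if not backgrounds:
        raise ValueError("scan set contains no background scan")
    ferrite = _single(scans, "ferrite")
    saline = _single(scans, "saline")

    def bundle_for(idx: int) -> CalibrationBundle:
        bg = backgrounds[0]
        for b in backgrounds:
            if b.scan_index <= idx:
                bg = b
        return CalibrationBundle(bg, ferrite, saline, saline_sigma, saline_eps_r)

    out = []
    for s in scans:
        if s.object_kind != "sample":
            continue
        cal = calibrate_scan(s, bundle_for(s.scan_index))
        out.append(invert_to_properties(cal))
    return out


def _single(scans: Sequence[RawScan], kind: str) -> RawScan:
    found = [s for s in scans if s.object_kind == kind]
    if len(found) != 1:
        raise ValueError(f"expected exactly one {kind} scan, found {len(found)}")
    return found[0]
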