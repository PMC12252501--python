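"""Tabular text I/O, configuration and the frequency grid.

All interchange is comma-separated UTF-8 text with a header row; complex
voltages are stored as paired real/imag columns.  Every table written by the
pipeline carries a ``# config_hash=...`` comment line so downstream stages
can refuse to mix tables produced under different configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

S_PER_M_TO_MS_PER_CM = 10.0  # 1 S/m = 10 mS/cm


def frequency_grid(n: int = 9, f_min: float = 100e3, f_max: float = 3e6) -> np.ndarray:
    """Logarithmically spaced sweep; defaults are the 9-point 100 kHz–3 MHz
    protocol.  Endpoints are exact; consecutive ratios are all equal."""
    if n < 2:
        raise ValueError("grid needs at least 2 points")
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    grid = np.geomspace(f_min, f_max, n)
    grid[0], grid[-1] = f_min, f_max
    return grid


@dataclass
class PipelineConfig:
    """Configuration of the full simulate→calibrate→analyse pipeline."""

    # frequency sweep
    n_freqs: int = 9
    f_min: float = 100e3
    f_max: float = 3e6
    # cohort
    n_samples: int = 60
    days: int = 22
    counts: dict[str, int] = field(default_factory=lambda: {"A": 8, "B": 4, "C": 48})
    jitter_cv: float = 0.4
    # instrument
    snr_db: float | None = 25.0
    drift_rate: float = 1e-3
    gain_mag: float = 2.0e3
    gain_phase_deg: float = 30.0
    background_scale: float = 1e-4
    sphere_radius_m: float = 0.03
    obs_distance_m: float = 0.08
    # calibration
    saline_sigma_s_per_m: float = 0.992
    saline_eps_r: float = 80.0
    # circuit fitting
    fit_model: str = "B"
    de_maxiter: int = 2000
    # clustering
    k_clusters: int = 3
    distance_mode: str = "dtw"
    # randomness
    seed: int = 0

    def grid(self) -> np.ndarray:
        return frequency_grid(self.n_freqs, self.f_min, self.f_max)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    """Write a CSV with an optional leading ``# config_hash=`` comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_table(path: str | Path, expect_hash: str | None = None) -> pd.DataFrame:
    """Read a pipeline CSV, verifying its config hash when one is expected."""
    path = Path(path)
    found = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        found = first.strip().split("=", 1)[1]
    if expect_hash is not None and found is not None and found != expect_hash:
        raise ValueError(
            f"{path} was produced under config {found}, expected {expect_hash}"
        )
    return pd.read_csv(path, comment="#")


def scans_to_frame(scans: Sequence[Any]) -> pd.DataFrame:
    """Serialize RawScan objects to the long tabular layout."""
    rows = []
    for s in scans:
        for f, v in zip(s.freqs, s.voltages):
            rows.append({
                "object_kind": s.object_kind,
                "sample_id": s.sample_id if s.sample_id is not None else "",
                "scan_index": s.scan_index,
                "day": s.day,
                "frequency_hz": f,
                "v_real": v.real,
                "v_imag": v.imag,
            })
    return pd.DataFrame(rows)


def frame_to_scans(df: pd.DataFrame) -> list:
    """Inverse of :func:`scans_to_frame`."""
    from .synthetic import RawScan

    scans = []
    df = df.copy()
    # empty sample_id cells (calibration objects) read back as NaN
    df["sample_id"] = df["sample_id"].fillna("")
    keys = ["object_kind", "sample_id", "scan_index", "day"]
    for (kind, sid, idx, day), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("frequency_hz")
        scans.append(RawScan(
            object_kind=str(kind),
            sample_id=None if sid == "" else str(sid),
            scan_index=int(idx),
            day=int(day),
            freqs=grp["frequency_hz"].to_numpy(),
            voltages=(grp["v_real"].to_numpy() + 1j * grp["v_imag"].to_numpy()),
        ))
    return scans


def spectra_to_frame(specs: Sequence[Any]) -> pd.DataFrame:
    """PropertySpectrum list -> table with S/m and paper-facing mS/cm columns."""
    rows = []
    for sp in specs:
        for f, s, e, q in zip(sp.freqs, sp.sigma, sp.eps_r, sp.quality):
            rows.append({
                "sample_id": sp.sample_id,
                "day": sp.day,
                "frequency_hz": f,
                "sigma_S_per_m": s,
                "sigma_mS_per_cm": s * S_PER_M_TO_MS_PER_CM,
                "eps_r": e,
                "quality_flag": bool(q),
            })
    return pd.DataFrame(rows)


def frame_to_spectra(df: pd.DataFrame) -> list:
    from .dispersion import PropertySpectrum

    specs = []
    for (sid, day), grp in df.groupby(["sample_id", "day"], sort=False):
        grp = grp.sort_values("frequency_hz")
        specs.append(PropertySpectrum(
            sample_id=str(sid),
            day=int(day),
            freqs=grp["frequency_hz"].to_numpy(),
            sigma=grp["sigma_S_per_m"].to_numpy(),
            eps_r=grp["eps_r"].to_numpy(),
            quality=grp["quality_flag"].to_numpy(dtype=bool)
            if "quality_flag" in grp else None,
        ))
    return specs
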