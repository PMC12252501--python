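# misripe

Magnetic induction spectroscopy (MIS) analysis of fruit ripening.

MIS measures the electrical conductivity σ(ω) and relative permittivity
εr(ω) of a sample without contact: an excitation coil drives an alternating
magnetic field B₁, eddy currents induced in the sample re-emit a secondary
field B₂, and the complex ratio B₂/B₁ across a frequency sweep carries the
material properties. In the β-dispersion band (here 100 kHz – 3 MHz) those
properties are dominated by cell-membrane polarisation, so they track the
physiological state of plant tissue — a climacteric fruit such as an
avocado shows a characteristic flattening of its conductivity spectrum as
membranes degrade during ripening.

`misripe` implements the full analysis chain for such a study as a tested,
reusable Python package, for researchers in biosensing / bioimpedance who
want to simulate, calibrate, and analyse MIS ripening data:

* **Forward model** — for a conductive, permittive sphere in a uniform AC
  field, `B₂/B₁ = −j₂(ka)/j₀(ka) · a³(r²−3z²)/(2r⁵)` with
  `k² = μ₀ε₀εrω² − jμ₀σω`; in the low-induction limit this reduces to
  `B₂/B₁ = P μ₀ω(ε₀εrω − jσ)`, `P = a⁵(3z²−r²)/(30r⁵)`.
* **Synthetic cohort** — ground-truth Cole–Cole ripening trajectories
  (ε\*(ω) = ε∞ + (εs−ε∞)/(1+(jωτ)^(1−α)) plus a DC conduction term) in
  three archetypes, wrapped in an instrument simulator with gain/phase
  error, background coupling, drift and configurable-SNR noise.
* **Calibration and inversion** — background subtraction, ferrite phase
  reference, saline magnitude reference, then
  σ(ω) = −Im S/(μ₀ω), εr(ω) = Re S/(μ₀ε₀ω²).
* **Dispersion metrics** — the normalised conductivity gradient
  `Py = (σ̂(3 MHz) − σ̂(100 kHz)) / σ̂(3 MHz)`, Cole-plane trajectories and
  three-stage ripening segmentation.
* **Equivalent circuits** — Hayden, Modified Hayden (CPE), Cole circuit and
  single-Cole impedance models fitted to the conductivity component by
  Differential Evolution with a scale-free RMSE cost.
* **Cohort statistics and clustering** — Pearson correlation with day,
  two-way sum-of-squares variance decomposition (between-sample share ρ),
  Tukey IQR outliers, and Min-Max → first-difference → DTW → PCA → GMM
  classification of ripening patterns.

## Worked example

Run the default study configuration — 60 fruit (8 stable "A" / 4
fast-ripening "B" / 48 typical "C"), scanned daily for 22 days on a 9-point
logarithmic sweep from 100 kHz to 3 MHz at 25 dB SNR:

```sh
misripe run-all --seed 1 --out-dir out
```

prints

```
pipeline complete; report at out/report.json
  terminal Py (mean spectrum): 0.525
  Pearson r(Py, day): -0.969
  rho (between-sample share): 0.606
```

and writes `scans.csv`, `spectra.csv`, `py.csv`, `daily_summary.csv`,
`circuit_fits.csv`, `clusters.csv` and `report.json`. Reading the report:
the cohort-mean Py falls from 0.82 on day 0 to about 0.52 at day 21 — the
conductivity spectrum flattens as membranes lose integrity; the strong
negative Pearson correlation says Py tracks ripening day almost
monotonically; ρ ≈ 0.61 says that roughly 61 % of the total Py variability
is fruit-to-fruit individuality rather than ripening trend or noise; and
the cluster table assigns each fruit one of the three ripening patterns.

Every stage is also exposed individually (`misripe simulate | invert | py |
fit | stats | cluster`) and as library functions, e.g.

```python
import misripe as m

grid = m.frequency_grid()                      # 9 points, 100 kHz - 3 MHz
truth = m.generate_cohort(60, {"A": 8, "B": 4, "C": 48}, rng_seed=1)
inst = m.default_instrument(grid, snr_db=25.0)
scans = m.simulate_scan_set(truth, inst, grid, day=0)
spectra = m.process_scan_set(scans, saline_sigma=0.992)
print(m.compute_py(spectra[0]).py)
```

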