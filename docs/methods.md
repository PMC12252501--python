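# Methods

## Physical forward model

A non-magnetic sphere (radius `a`, conductivity σ, relative permittivity
εr) in a uniform oscillating field perturbs it through induced eddy
currents. The axial secondary-to-primary field ratio at an observation
point at distance `r` from the sphere centre (axial component `z`) is

    B2/B1 = −[j2(ka)/j0(ka)] · a³(r² − 3z²)/(2r⁵),
    k² = μ0 ε0 εr ω² − j μ0 σ ω.

For fruit tissue over 100 kHz – 3 MHz, |ka| ≲ 0.2, far below the skin-effect
regime, and the Bessel ratio is within a fraction of a percent of its
leading term (ka)²/15, giving the first-order model

    B2/B1 = P μ0 ω (ε0 εr ω − j σ),   P = a⁵(3z² − r²)/(30 r⁵).

Conventions and numerics:

* `r` is the **spherical** distance from the sphere centre and `z` its
  axial component (|z| ≤ r). This is the reading under which the positional
  factor is exactly an induced-dipole field; the equatorial (z = 0) and
  on-axis (z = r) cases bracket the geometry. P is homogeneous of degree 2
  in (a, r, z) — it carries units m², cancelling the 1/m² of k².
* `k = √(k²)` uses the principal branch, but nothing downstream depends on
  the branch: j2/j0 is an even function, evaluated directly in k²a².
* Exact Bessel mode uses `scipy.special.spherical_jn` for real argument and
  a six-term even power-series ratio for complex argument (relative error
  < 1e−12 for |ka| < 1); this avoids unstable complex Bessel evaluations.
* Internal units are SI throughout; mS/cm appears only in I/O columns
  (1 mS/cm = 0.1 S/m).

## Tissue model

Tissue permittivity follows a single Cole–Cole relaxation

    ε*(ω) = ε∞ + (εs − ε∞) / (1 + (jωτ)^(1−α)),

with the relaxation term read as *relative* permittivity. Because real
tissue shows nonzero low-frequency conductivity that a pure relaxation term
cannot produce, the model is extended with an explicit DC ionic conduction
term:

    σ(ω) = σ_dc + ω ε0 (−Im ε*(ω)),   εr(ω) = Re ε*(ω).

This extension is a modelling choice of this package, made so that the
generated spectra exhibit both the β-dispersion shape and realistic
low-frequency conductivity levels simultaneously.

The flatness statistic is the normalised conductivity gradient

    Py = (σ̂(f_high) − σ̂(f_low)) / σ̂(f_high),

evaluated at the sweep endpoints (100 kHz, 3 MHz) without interpolation.
Py is invariant under multiplicative rescaling of the whole spectrum, so it
compensates for sample-size/geometry factors. Cole-plane trajectories plot
(εr, σ/(ωε0)) per frequency per day — the permittivity plane, chosen for
unit consistency with the property spectra; ripening drives the locus
toward smaller real and larger imaginary coordinates.

## Synthetic cohort generator

The generator emulates a 60-fruit cohort measured daily for 22 days, split
8/4/48 into three ripening archetypes:

* **A (stable)** — Py within ±0.05 of 0.80 for the whole period; the
  conductivity level dips to day 15 then recovers.
* **B (fast ripeners)** — Py declines monotonically from 0.85 to 0.38; the
  high-frequency conductivity peaks near day 15 then falls.
* **C (typical, 80 %)** — Py ≈ 0.825 at day 0, fast decline to day 5,
  plateau on days 5–15, sharp drop to 0.50 by day 21. C's endpoint
  conductivities are anchored at σ(100 kHz)/σ(3 MHz) = 0.20/1.14 S/m on day
  0 and 0.59/1.18 S/m on day 21, the cohort-mean values of the study this
  package models. A and B carry no published absolute levels; their anchors
  encode the qualitative shape only and must not be read as measurements.

Anchors at days 0/5/15/21 are interpolated linearly onto the day grid and
back-solved into Cole–Cole parameters: for fixed (τ = 1.6e−7 s, α = 0.20,
ε∞ = 20) the two endpoint-conductivity constraints are linear in
(σ_dc, εs − ε∞) and solved exactly, so the implied Py series hits the
archetype shape by construction. τ places the relaxation mid-band; α = 0.20
is a typical broadening for plant tissue; the resulting εs of order 10⁴ is
the expected β-dispersion magnitude.

Per-fruit individuality: σ_dc and the dispersion strength εs − ε∞ are
multiplied by independent log-normal factors (unit mean), constant across
days. The default coefficient of variation is 0.4, chosen so that the
noise-free cohort's two-way variance decomposition of Py attributes ≈ 0.61
of the total sum of squares to between-sample differences — the
individuality share the modelled study reports. Consequence worth noting:
this CV implies a wider absolute conductivity spread than the study's
printed day-0 cohort mean ± spread; the variance-share calibration was
given priority.

Instrument layer: each scan is

    v(ω) = gain(ω)·(1 + drift·scan_index)·(B2/B1)(ω) + background(ω) + n(ω),

with the exact Bessel forward model, default gain 2000·e^{j30°}, a smooth
frequency-dependent background offset, linear drift 1e−3 per scan index,
and i.i.d. complex Gaussian noise per frequency scaled so the power SNR of
the scan's own signal term equals `snr_db` (default 25 dB; the modelled
instrument's floor is 20 dB). Background and calibration scans are treated
as heavily averaged (noise-free) unless `noisy_calibration` is set; the
background scan has no sample term to reference noise against. Each scan
session emits background, ferrite (frequency-flat, purely real, positive
intrinsic response — a non-conductive permeable rod needs no magnetic
forward model, only the phase-reference idealisation), and a saline sphere
(flat σ = 0.992 S/m, εr = 80).

What the generator does **not** emulate: mass loss and shrinkage,
temperature dependence, sample mispositioning, the parasitic-capacitance
SNR resonance of a real coil, multi-dispersion (α+β+γ) tissue, and
non-spherical sample shapes. Passing tests therefore demonstrate the
correctness and robustness of the analysis chain under the stated model,
not instrument-grade validation on real fruit.

## Calibration and inversion

Background subtraction removes the additive coupling; the ferrite scan's
phase (after background subtraction) is pure system phase and is rotated
away; the saline scan pins the absolute complex scale per frequency,
c(ω) = model(saline)/measured(saline) with the first-order model at P = 1.
Per-frequency (not single-scalar) magnitude calibration is used because
real receive chains have frequency-dependent gain; for the ideal simulator
the two coincide. The saline's relative permittivity is taken as 80
(water). Inversion is then algebraic: σ = −Im S/(μ0ω), εr = Re S/(μ0ε0ω²).

Because the simulator's forward model is exact while the inversion is
first-order, a noiseless round trip carries an O((ka)²) bias; at the
default geometry (a = 3 cm, r = z = 8 cm) this is < 1 % in σ and < 5 % in
εr, and mostly cancels against the saline reference's own bias. Negative
inverted σ or εr (noise at low frequency) are retained with a quality flag
rather than clipped so downstream statistics see unbiased noise. Sample
scans use the nearest *preceding* background scan, honouring mid-session
background re-measurement without interpolation.

## Equivalent circuits

The four topologies (extracellular resistance R2 parallel to an
intracellular branch; CPE Z = 1/(Q(jω)^α)):

    A: Y = 1/R2 + 1/(R1 + 1/(jωC))           (Hayden)
    B: Y = 1/R2 + 1/(R1 + Z_CPE)             (Modified Hayden)
    C: Z = R∞ + ΔR/(1 + ΔR·Q(jω)^α), Y = 1/Z (Cole circuit)
    D: Z = R∞ + (R0−R∞)/(1+(jωτ)^(1−α))      (single Cole)

These assignments follow standard bioimpedance practice (the parameter sets
R1, R2, CPE_q, CPE_a and the 4–5 parameter count); the topologies are
explicit package conventions and configurable. A cell constant κ maps
admittance to effective conductivity, σ* = κY; with κ absorbed into the
resistances, fits are invariant to it. Only Re σ* is fitted — the
permittivity channel is too noisy at low frequency to constrain the fit.

Differential Evolution: rand/1/bin, F = 0.8, CR = 0.9, population 15×dim,
tol 1e−8, max 2000 generations, Sobol initialisation, L-BFGS-B polish,
fixed seed. Scale parameters are searched in log space over [1e−3, 1e3]×
the data-implied scale (bounds configurable); exponents over [0, 1]. The
cost is RMSE divided by the RMS of the measured conductivity, reported in
percent, making fit quality scale-free; the normalisation choice is the
package's own. A flat spectrum is fitted degenerately (resistor-only
solution) rather than rejected.

## Statistics

* Pearson r with a two-sided p from the t transform (n−2 d.o.f.); p-values
  are descriptive, no multiple-testing correction.
* Variance decomposition: two-way additive partition
  SS_total = SS_sample + SS_day + SS_residual on the balanced samples ×
  days Py matrix; ρ = SS_sample/SS_total. The two-way (rather than
  one-way) partition is used because individuality is contrasted against
  both temporal trend and residual noise; the partition is exact on every
  input.
* Tukey fences at 1.5·IQR with linear-interpolation quartiles (the common
  scientific-software default; configurable in principle since outlier
  counts depend on the convention). Constant data collapse the fences onto
  the constant.
* Daily summaries report both the mean of per-sample Py and the Py of the
  day's mean spectrum; the two differ whenever the high-frequency endpoint
  varies across samples, and both are legitimate cohort descriptors.

## Stage segmentation

The three ripening stages (pre-ripe, ripe, overripe) are found by a
continuous three-segment piecewise-linear least-squares fit to a Py series,
with breakpoints searched on the integer-day grid (each segment ≥ 2 days,
ties toward earlier breakpoints). A series that a single line fits equally
well (SSE improvement below 1e−3 of the series variance) is flagged
degenerate — its breakpoints are not meaningful. This is a formalisation
choice: the stage boundaries themselves are visually evident in cohort
data, but an explicit estimator makes them testable. On the default C-type
cohort the estimator recovers breaks at days 5 and 15.

## Clustering

Per-sample Py series are Min-Max normalised and first-differenced (level
and span removed, shape kept; constant series map to zero by convention).
Pairwise distances default to classic DTW with squared local cost
(optionally Sakoe–Chiba banded); an alternative mode aligns each pair along
its optimal warping path and takes the Euclidean norm of the aligned
difference. The distance matrix rows are reduced to two principal
components — a pragmatic embedding of the distance profile, not classical
MDS — and a 3-component full-covariance Gaussian mixture (10
initialisations, fixed seed) assigns clusters. k = 3 mirrors the three
observed ripening patterns; information-criterion selection is available
but off by default. Archetype naming: C = largest cluster, A = the
remaining cluster with the smaller mean absolute total Py change, B = the
other; size ties break toward the tighter cluster. DTW violates the
triangle inequality, so no metric properties beyond symmetry/non-negativity
are assumed anywhere.

## Problem sizes and tolerances

The package's own verification runs use: the full 60 × 22 cohort for
clustering and variance checks; 200 replicate scans for the 20 dB
inversion-error bound; 30–40 replicates for variance-share recovery; and a
median over 31 noise replicates for the circuit-fit quality figure (a
single 4-parameter fit of 9 noisy points retains only 5 residual degrees of
freedom, so per-draw RMSE scatters by ~30 % and a median is the stable
summary). Circuit fits in the pipeline are applied to the per-day mean
spectrum (22 fits), matching how cohort-level parameter trends are usually
reported. Noise at "x dB" always means power SNR of the scan's own signal
term; after inversion this leaves relative conductivity noise of
10^(−x/20)/√2 per frequency, since the imaginary quadrature carries half
the noise power.

## Known limitations

* The saline calibration object is idealised as a sphere of the same
  geometry as the samples; a real 150 mL volume folds its shape mismatch
  into c(ω).
* The first-order inversion biases σ by O((ka)²); negligible here but not
  for larger/saltier samples or higher frequencies.
* Archetype A/B absolute conductivity levels are invented (shape-only).
* The jitter CV that reproduces ρ ≈ 0.61 overstates the absolute
  conductivity spread relative to the modelled study's printed day-0 mean.
* Gain drift is linear in scan index and is not corrected by calibration
  (only background re-measurement); Py is immune (multiplicative), absolute
  σ is not.
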