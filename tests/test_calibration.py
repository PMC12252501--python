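"""Background/phase/magnitude calibration and property inversion tests."""

import numpy as np
import pytest

from misripe import (CalibrationBundle, CohortTruth, MaterialProperties,
                     calibrate_scan, cole_cole_spectrum, default_instrument,
                     field_ratio, generate_cohort, invert_to_properties,
                     lumped_field_ratio, magnitude_calibrate, phase_calibrate,
                     process_scan_set, simulate_scan_set, subtract_background)
from misripe.calibration import phase_rotations
from misripe.synthetic import RawScan


@pytest.fixture(scope="module")
def cal_scans(grid, clean_instrument):
    truth = CohortTruth(trajectories=(), proportions={}, seed=0)
    return simulate_scan_set(truth, clean_instrument, grid, 0)


@pytest.fixture(scope="module")
def bundle(cal_scans):
    bg = [s for s in cal_scans if s.object_kind == "background"][0]
    fe = [s for s in cal_scans if s.object_kind == "ferrite"][0]
    sa = [s for s in cal_scans if s.object_kind == "saline"][0]
    return CalibrationBundle(bg, fe, sa, saline_sigma=0.992)


def make_phantom(inst, grid, sigma=0.992, eps_r=80.0, scan_index=3):
    props = MaterialProperties(sigma, eps_r)
    sig = inst.gain_by_freq * np.array(
        [field_ratio(inst.geometry, props, f, mode="exact") for f in grid])
    return RawScan("sample", "phantom", scan_index, grid,
                   sig + inst.background_by_freq, 0)


class TestSubtractBackground:
    def test_background_minus_itself_is_zero(self, cal_scans, bundle):
        bg = [s for s in cal_scans if s.object_kind == "background"][0]
        out = subtract_background(bg, bundle)
        np.testing.assert_array_equal(out.voltages, 0.0)

    def test_linearity(self, grid, bundle):
        extra = (0.3 - 0.7j) * np.ones(len(grid))
        base = RawScan("sample", "s", 3, grid,
                       bundle.background.voltages + extra, 0)
        out = subtract_background(base, bundle)
        np.testing.assert_allclose(out.voltages, extra, rtol=1e-12)

    def test_grid_mismatch_rejected(self, bundle):
        other = RawScan("sample", "s", 3, [1e5, 2e5], [0j, 0j], 0)
        with pytest.raises(ValueError):
            subtract_background(other, bundle)

    def test_injected_background_removed_below_noise_floor(self, grid):
        # noisy simulation round trip: residual background stays below the
        # per-frequency noise level
        truth = generate_cohort(1, {"C": 1}, rng_seed=0)
        inst = default_instrument(grid, snr_db=30.0, drift_rate=0.0, seed=5)
        clean = default_instrument(grid, snr_db=None, drift_rate=0.0)
        scans = simulate_scan_set(truth, inst, grid, 0)
        ref = simulate_scan_set(truth, clean, grid, 0)
        bg = [s for s in scans if s.object_kind == "background"][0]
        sample = [s for s in scans if s.object_kind == "sample"][0]
        clean_sig = ([s for s in ref if s.object_kind == "sample"][0].voltages
                     - clean.background_by_freq)
        b = CalibrationBundle(bg, [s for s in scans
                                   if s.object_kind == "ferrite"][0],
                              [s for s in scans
                               if s.object_kind == "saline"][0], 0.992)
        resid = subtract_background(sample, b).voltages - clean_sig
        noise_floor = np.abs(clean_sig) * 10 ** (-30 / 20)
        assert np.all(np.abs(resid) < 5 * noise_floor)


class TestPhaseCalibrate:
    def test_ferrite_becomes_real_positive(self, bundle):
        fe = subtract_background(bundle.ferrite, bundle)
        out = phase_calibrate(fe, bundle)
        assert np.all(np.abs(out.voltages.imag)
                      <= 1e-12 * np.abs(out.voltages))
        assert np.all(out.voltages.real > 0)

    def test_recalibration_from_calibrated_bundle_is_identity(self, bundle,
                                                              grid):
        # after one pass the ferrite is already real: a bundle rebuilt from
        # calibrated scans induces (numerically) zero further rotation
        bg0 = RawScan("background", None, 0, grid,
                      np.zeros(len(grid), complex), 0)
        fe1 = phase_calibrate(subtract_background(bundle.ferrite, bundle),
                              bundle)
        sa1 = phase_calibrate(subtract_background(bundle.saline, bundle),
                              bundle)
        bundle2 = CalibrationBundle(bg0, fe1, sa1, 0.992)
        assert np.max(np.abs(phase_rotations(bundle2))) < 1e-12

    def test_recovers_configured_system_phase(self, grid):
        inst = default_instrument(grid, gain_phase_deg=30.0, snr_db=None)
        truth = CohortTruth(trajectories=(), proportions={}, seed=0)
        scans = simulate_scan_set(truth, inst, grid, 0)
        b = CalibrationBundle(scans[0], scans[1], scans[2], 0.992)
        np.testing.assert_allclose(np.rad2deg(phase_rotations(b)), 30.0,
                                   rtol=1e-9)

    def test_zero_ferrite_response_fails(self, bundle, grid):
        dead = RawScan("ferrite", None, 1, grid,
                       bundle.background.voltages.copy(), 0)
        bad = CalibrationBundle(bundle.background, dead, bundle.saline, 0.992)
        with pytest.raises(ValueError, match="ferrite"):
            phase_rotations(bad)


class TestMagnitudeCalibrate:
    def test_saline_maps_to_model_ratio(self, bundle):
        cal = magnitude_calibrate(
            phase_calibrate(subtract_background(bundle.saline, bundle),
                            bundle), bundle)
        expected = np.array([
            lumped_field_ratio(MaterialProperties(0.992, 80.0), f)
            for f in bundle.saline.freqs])
        np.testing.assert_allclose(cal.voltages, expected, rtol=1e-12)

    def test_per_frequency_gain_error_compensated(self, grid):
        inst = default_instrument(grid, snr_db=None, drift_rate=0.0)
        gain = inst.gain_by_freq.copy()
        gain[4] *= 2.0  # gain spike at one frequency
        inst2 = type(inst)(gain_by_freq=gain,
                           background_by_freq=inst.background_by_freq,
                           geometry=inst.geometry, drift_rate=0.0,
                           snr_db=None, seed=0)
        truth = CohortTruth(trajectories=(), proportions={}, seed=0)
        specs = []
        for instrument in (inst, inst2):
            scans = simulate_scan_set(truth, instrument, grid, 0)
            b = CalibrationBundle(scans[0], scans[1], scans[2], 0.992)
            phantom = make_phantom(instrument, grid, sigma=0.5)
            specs.append(invert_to_properties(calibrate_scan(phantom, b)))
        # the spike cancels exactly; only the (identical) small saline-vs-
        # sample forward-model bias remains in both
        np.testing.assert_allclose(specs[1].sigma, specs[0].sigma, rtol=1e-12)
        assert np.max(np.abs(specs[0].sigma / 0.5 - 1)) < 1e-3

    def test_nonpositive_saline_conductivity_rejected(self, bundle):
        with pytest.raises(ValueError):
            CalibrationBundle(bundle.background, bundle.ferrite,
                              bundle.saline, saline_sigma=0.0)


class TestInversion:
    def test_algebraic_inverse_at_single_frequency(self):
        s = lumped_field_ratio(MaterialProperties(1.0, 80.0), 1e6)
        scan = RawScan("sample", "s", 0, [1e6], [s], 0)
        spec = invert_to_properties(scan)
        assert spec.sigma[0] == pytest.approx(1.0, rel=1e-14)
        assert spec.eps_r[0] == pytest.approx(80.0, rel=1e-12)

    def test_noiseless_saline_phantom_full_chain(self, grid, clean_instrument,
                                                 bundle):
        phantom = make_phantom(clean_instrument, grid)
        spec = invert_to_properties(calibrate_scan(phantom, bundle))
        np.testing.assert_allclose(spec.sigma, 0.992, rtol=1e-12)
        assert not spec.quality.any()

    def test_negative_outputs_flagged_not_clipped(self, grid):
        voltages = np.full(len(grid), 1e-9 + 1e-9j)  # positive Im -> sigma<0
        spec = invert_to_properties(RawScan("sample", "s", 0, grid, voltages, 0))
        assert np.all(spec.sigma < 0)
        assert spec.quality.all()

    def test_round_trip_tissue_recovery(self, grid, clean_instrument):
        # exact forward + first-order inversion: O((ka)^2) bias only
        truth = generate_cohort(3, {"A": 1, "B": 1, "C": 1}, rng_seed=2)
        scans = simulate_scan_set(truth, clean_instrument, grid, day=4)
        specs = process_scan_set(scans, 0.992)
        assert len(specs) == 3
        for traj, spec in zip(truth.trajectories, specs):
            gt = cole_cole_spectrum(traj.params_by_day[4], grid)
            assert np.max(np.abs(spec.sigma / gt.sigma - 1)) < 0.01
            assert np.max(np.abs(spec.eps_r / gt.eps_r - 1)) < 0.05

    def test_inversion_error_decreases_with_snr(self, grid):
        truth = generate_cohort(1, {"C": 1}, rng_seed=0)
        errs = []
        for snr in (15.0, 25.0, 35.0):
            med = []
            for rep in range(40):
                inst = default_instrument(grid, snr_db=snr, drift_rate=0.0,
                                          seed=rep)
                scans = simulate_scan_set(truth, inst, grid, 0)
                spec = process_scan_set(scans, 0.992)[0]
                gt = cole_cole_spectrum(truth.trajectories[0].params_by_day[0],
                                        grid)
                med.append(np.median(np.abs(spec.sigma / gt.sigma - 1)))
            errs.append(np.median(med))
        assert errs[0] > errs[1] > errs[2]

    def test_nearest_preceding_background_used(self, grid, clean_instrument):
        # a second background taken mid-session applies to later samples only
        truth = generate_cohort(2, {"C": 2}, rng_seed=0)
        scans = simulate_scan_set(truth, clean_instrument, grid, 0)
        shifted_bg = RawScan(
            "background", None, 4, grid,
            clean_instrument.background_by_freq * 1.5, 0)
        # recompute second sample's voltage as if background had drifted
        s2 = scans[-1]
        drifted = RawScan(
            s2.object_kind, s2.sample_id, s2.scan_index, grid,
            s2.voltages + 0.5 * clean_instrument.background_by_freq, 0)
        specs = process_scan_set(list(scans[:-1]) + [shifted_bg, drifted],
                                 0.992)
        gt = cole_cole_spectrum(truth.trajectories[1].params_by_day[0], grid)
        assert np.max(np.abs(specs[1].sigma / gt.sigma - 1)) < 0.01
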