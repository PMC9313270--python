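"""Unit and property tests for the streaming quantification algorithm."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from peakfluo import ampsim, core, triplicate_panel
from peakfluo.core import (
    CleanedTrace,
    PeakFluoParams,
    StandardCurve,
    average_replicates,
    brute_force_peak,
    clean_trace,
    estimate_background,
    find_peak,
    fit_standard_curve,
    quantify,
    quantify_two_point_raw,
    run_peakfluo,
    validate_assay,
)
from peakfluo.errors import FlatCurveError, TraceMismatchError
from peakfluo.trace import FluorescenceTrace


def make_trace(values, well_id="w", start=1):
    values = np.asarray(values, dtype=float)
    return FluorescenceTrace(well_id, np.arange(start, start + len(values)), values)


def make_cleaned(values, start=11, well_id="w"):
    values = np.asarray(values, dtype=float)
    return CleanedTrace(well_id, np.arange(start, start + len(values)), values)


def group_mean(traces, layout, group):
    by_id = {t.well_id: t for t in traces}
    return average_replicates([by_id[w.well_id] for w in layout.wells_in(group)])


class TestEstimateBackground:
    def test_constant_trace(self):
        tr = make_trace([7.5] * 20)
        assert estimate_background(tr) == 7.5
        assert estimate_background(tr, mode="max") == 7.5

    def test_arithmetic_example(self):
        tr = make_trace(list(range(1, 11)) + [100] * 10)
        assert estimate_background(tr, (1, 10), "mean") == 5.5
        assert estimate_background(tr, (1, 10), "max") == 10

    def test_simulated_pre_onset_closed_form(self):
        cfg = ampsim.SimConfig(
            noise_sd_well=0.0,
            noise_sd_process=0.0,
            baseline_drift=0.3,
            y0_control=1.0,
            efficiency_E=1.0,
            detection_threshold_copies=1e12,
        )
        tr = ampsim.simulate_trace(0.0, cfg)
        want = cfg.baseline_level + cfg.baseline_drift * np.mean(np.arange(1, 11))
        assert estimate_background(tr) == pytest.approx(want, abs=1e-6)

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(make_trace([1.0] * 5), (1, 10))


class TestCleanTrace:
    def test_control_against_itself_is_zero(self, noise_free_cfg):
        ctrl = ampsim.simulate_trace(0.0, noise_free_cfg)
        cleaned = clean_trace(ctrl, ctrl)
        np.testing.assert_allclose(cleaned.values, 0.0, atol=1e-12)

    def test_identical_traces_equal_backgrounds(self):
        tr = make_trace(np.linspace(1, 30, 30))
        np.testing.assert_allclose(clean_trace(tr, tr).values, 0.0, atol=1e-12)

    def test_dip_shape_against_control(self, noise_free_cfg):
        # near zero early, negative dip while the control rises first, back
        # toward zero at the shared plateau
        ctrl = ampsim.simulate_trace(0.0, noise_free_cfg)
        sample = ampsim.simulate_trace(10.0, noise_free_cfg)
        cleaned = clean_trace(sample, ctrl)
        assert abs(cleaned.values[0]) < 0.05 * noise_free_cfg.amplitude
        assert cleaned.values.min() < -0.3 * noise_free_cfg.amplitude
        assert cleaned.values[-1] > 0.1 * cleaned.values.min()  # recovered near 0

    def test_mismatched_grids_rejected(self):
        with pytest.raises(TraceMismatchError):
            clean_trace(make_trace([1.0] * 20), make_trace([1.0] * 25))

    def test_start_cycle_respected(self, noise_free_cfg):
        ctrl = ampsim.simulate_trace(0.0, noise_free_cfg)
        cleaned = clean_trace(ampsim.simulate_trace(1.0, noise_free_cfg), ctrl)
        assert cleaned.cycles[0] == 11
        assert len(cleaned.values) == noise_free_cfg.n_cycles - 10


class TestFindPeak:
    def test_hand_traceable_stream(self):
        cleaned = make_cleaned([0, 0, -1, -3, -5, -4, -2, 0])
        result = find_peak(cleaned, persistence=2)
        assert result.peak_magnitude == 5
        assert result.peak_cycle == 15
        assert result.stop_cycle == 17
        assert result.found

    def test_monotone_decreasing_not_found(self):
        cleaned = make_cleaned([-1, -2, -3, -4, -5])
        result = find_peak(cleaned, persistence=2)
        assert not result.found
        assert result.peak_cycle == 15  # last cycle
        assert result.peak_magnitude == 5

    def test_tie_first_occurrence_wins(self):
        cleaned = make_cleaned([0, -4, -2, -4, 1, 2, 3])
        result = find_peak(cleaned, persistence=3)
        assert result.peak_cycle == 12
        assert result.peak_magnitude == 4

    def test_start_cycle_past_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            find_peak(make_cleaned([0, 1, 2]), start_cycle=99)

    def test_noise_free_equals_brute_force(self, noise_free_cfg, panel):
        traces = ampsim.simulate_plate(panel, noise_free_cfg)
        ctrl = group_mean(traces, panel, "control")
        for t in traces:
            if t.well_id.startswith("NC"):
                continue  # control cleaned trace is zero up to float dust
            cleaned = clean_trace(t, ctrl)
            streamed = find_peak(cleaned, persistence=3)
            oracle = brute_force_peak(cleaned)
            assert streamed.peak_magnitude == oracle.peak_magnitude
            assert streamed.peak_cycle == oracle.peak_cycle

    def test_noisy_agreement_rate(self, default_cfg, panel):
        agree = total = 0
        for seed in range(17):  # 17 plates x 12 non-control wells = 204 wells
            traces = ampsim.simulate_plate(panel, default_cfg, seed=seed)
            ctrl = group_mean(traces, panel, "control")
            for t in traces:
                if t.well_id.startswith("NC"):
                    continue
                cleaned = clean_trace(t, ctrl)
                streamed = find_peak(cleaned, persistence=3)
                oracle = brute_force_peak(cleaned)
                total += 1
                agree += int(
                    streamed.peak_magnitude == oracle.peak_magnitude
                    and streamed.peak_cycle == oracle.peak_cycle
                )
        assert total >= 200
        assert agree / total >= 0.95

    @given(
        values=st.lists(
            st.floats(-100, 100, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=40,
        )
    )
    def test_full_scan_matches_global_minimum(self, values):
        # persistence longer than the trace can never fire early, so the
        # stream must report exactly the brute-force global minimum
        cleaned = make_cleaned(values)
        streamed = find_peak(cleaned, persistence=len(values) + 1)
        oracle = brute_force_peak(cleaned)
        assert streamed.peak_magnitude == oracle.peak_magnitude
        assert streamed.peak_cycle == oracle.peak_cycle
        assert not streamed.found

    def test_early_stop_economy_on_noise_free_plate(self, noise_free_cfg, panel):
        traces = ampsim.simulate_plate(panel, noise_free_cfg)
        ctrl = group_mean(traces, panel, "control")
        for t in traces:
            if t.well_id.startswith("NC"):
                continue  # control cleaned trace is identically zero
            result = find_peak(clean_trace(t, ctrl), persistence=3)
            assert result.found
            assert result.stop_cycle < noise_free_cfg.n_cycles


class TestAverageReplicates:
    def test_single_trace_identity(self):
        tr = make_trace([1, 2, 3])
        np.testing.assert_array_equal(
            average_replicates([tr]).fluorescence, tr.fluorescence
        )

    def test_symmetric_cancellation(self):
        x = np.linspace(-5, 5, 12)
        avg = average_replicates([make_trace(x, "a"), make_trace(-x, "b")])
        np.testing.assert_allclose(avg.fluorescence, 0.0, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            average_replicates([])

    def test_triplicate_noise_reduction(self):
        sigma = 5.0
        cfg = ampsim.SimConfig(noise_sd_well=sigma, noise_sd_process=0.0)
        clean_cfg = cfg.model_copy(update={"noise_sd_well": 0.0})
        truth = ampsim.simulate_trace(1.0, clean_cfg).fluorescence
        rng = np.random.default_rng(0)
        residuals = []
        for _ in range(200):
            reps = [
                ampsim.simulate_trace(1.0, cfg, None, rng, well_id=f"r{i}")
                for i in range(3)
            ]
            residuals.append(average_replicates(reps).fluorescence - truth)
        observed = np.std(np.concatenate(residuals))
        assert observed == pytest.approx(sigma / np.sqrt(3), rel=0.2)


class TestValidateAssay:
    def test_all_nonpositive_valid(self):
        cleaned = [make_cleaned([0, -1, -5, -3, -1, 0])]
        assert validate_assay(cleaned)

    def test_empty_list_vacuously_valid(self):
        assert validate_assay([])

    def test_swapped_template_flagged(self, noise_free_cfg):
        # "control" simulated with less template than the sample: the sample
        # amplifies first, its cleaned signal rises above +tolerance
        fake_control = ampsim.simulate_trace(1.0, noise_free_cfg, well_id="NC")
        sample = ampsim.simulate_trace(0.0, noise_free_cfg, well_id="U")
        cleaned = clean_trace(sample, fake_control)
        assert not validate_assay([cleaned], tolerance=25.0)

    def test_tolerance_respected(self):
        bump = make_cleaned([0, 10, 0, -40, -20, 0])
        assert validate_assay([bump], tolerance=25.0)
        assert not validate_assay([bump], tolerance=5.0)


class TestStandardCurve:
    def test_two_point_line(self):
        curve = fit_standard_curve([(0.1, 2.0), (10.0, 6.0)])
        assert curve.slope == pytest.approx(2.0)
        assert curve.r_squared is None
        assert quantify(2.0, curve) == pytest.approx(0.1, rel=1e-9)
        assert quantify(6.0, curve) == pytest.approx(10.0, rel=1e-9)

    def test_collinear_r_squared_one(self):
        curve = fit_standard_curve([(0.1, 1.0), (1.0, 3.0), (10.0, 5.0)])
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_replicates_averaged_per_concentration(self):
        curve = fit_standard_curve([(1.0, 2.0), (1.0, 4.0), (10.0, 6.0)])
        assert dict(curve.fit_points)[0.0] == pytest.approx(3.0)

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(1.0, 2.0), (1.0, 3.0)])

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(0.0, 1.0), (1.0, 2.0)])

    def test_noise_free_panel_linearity(self, noise_free_cfg, standards_panel):
        traces = ampsim.simulate_plate(standards_panel, noise_free_cfg)
        result = run_peakfluo(traces, standards_panel)
        assert result.curve.r_squared >= 0.99


class TestQuantify:
    def test_midpoint_gives_geometric_mean(self):
        curve = fit_standard_curve([(0.1, 2.0), (10.0, 6.0)])
        mid = quantify(4.0, curve)
        assert mid == pytest.approx(np.sqrt(0.1 * 10.0), rel=1e-9)

    def test_flat_curve_rejected(self):
        curve = StandardCurve(0.0, 1.0, None, ((np.log10(0.1), 1.0), (1.0, 1.0)))
        with pytest.raises(FlatCurveError):
            quantify(1.0, curve)

    def test_two_point_raw_pseudocode_form(self):
        conc = quantify_two_point_raw(3.0, (1.0, 2.0), (10.0, 6.0))
        # exact line through the raw-concentration points
        assert conc == pytest.approx(1.0 + (3.0 - 2.0) / ((6.0 - 2.0) / 9.0), rel=1e-12)

    @given(
        peak1=st.floats(1, 100),
        peak2=st.floats(1, 100),
        sample=st.floats(1, 100),
    )
    def test_calibration_identity_two_point(self, peak1, peak2, sample):
        if abs(peak1 - peak2) < 1e-3:
            return
        curve = fit_standard_curve([(0.1, peak1), (10.0, peak2)])
        assert quantify(peak1, curve) == pytest.approx(0.1, rel=1e-6)
        assert quantify(peak2, curve) == pytest.approx(10.0, rel=1e-6)


class TestRunPeakFluo:
    def test_noise_free_recovery(self, tuned_noise_free_cfg, panel):
        traces = ampsim.simulate_plate(panel, tuned_noise_free_cfg)
        result = run_peakfluo(traces, panel)
        assert result.valid_assay
        truth = {"unk1": 0.3, "unk2": 3.0}
        for group, want in truth.items():
            est = result.samples[group].estimated_concentration
            assert abs(np.log10(est) - np.log10(want)) < 0.05

    def test_control_nullity(self, noise_free_cfg, panel):
        traces = ampsim.simulate_plate(panel, noise_free_cfg)
        result = run_peakfluo(traces, panel)
        assert result.control_peak.peak_magnitude == pytest.approx(0.0, abs=1e-9)

    def test_peak_monotone_in_concentration(self, noise_free_cfg, panel):
        traces = ampsim.simulate_plate(panel, noise_free_cfg)
        result = run_peakfluo(traces, panel)
        peaks = [
            result.standards[g].peak.peak_magnitude for g in ("std1", "std2", "std3")
        ]
        assert peaks[0] < peaks[1] < peaks[2]

    def test_adversarial_plate_flagged_invalid(self, noise_free_cfg, panel):
        # simulate the control wells with *less* template than one sample
        traces = []
        for w in panel.wells:
            conc = 1.0 if w.role == "control" else (0.0 if w.replicate_group == "unk1" else w.concentration)
            traces.append(
                ampsim.simulate_trace(conc, noise_free_cfg, well_id=w.well_id)
            )
        result = run_peakfluo(traces, panel)
        assert not result.valid_assay
        assert all(q.estimated_concentration is None for q in result.samples.values())

    def test_pure_baseline_plate_flat_curve_error(self, panel):
        cycles = np.arange(1, 41)
        traces = [
            FluorescenceTrace(w.well_id, cycles, np.full(40, 100.0))
            for w in panel.wells
        ]
        with pytest.raises(FlatCurveError):
            run_peakfluo(traces, panel)

    def test_replicate_peaks_reported(self, default_cfg, panel):
        traces = ampsim.simulate_plate(panel, default_cfg, seed=5)
        result = run_peakfluo(traces, panel)
        for q in list(result.standards.values()) + list(result.samples.values()):
            assert len(q.replicate_peaks) == 3


class TestParams:
    def test_start_cycle_must_clear_background_window(self):
        with pytest.raises(ValueError):
            PeakFluoParams(background_window=(1, 10), start_cycle=10)

    def test_bad_persistence(self):
        with pytest.raises(ValueError):
            PeakFluoParams(persistence=0)
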