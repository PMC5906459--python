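"""Quantification pipelines: carryover arithmetic, ΔF/F0, Hill fit, screen
statistics, staining summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import wellflux as wf
from wellflux import analysis
from wellflux.analysis import AnalysisError


class TestRoiMeanIntensity:
    def test_uniform_frames(self):
        assert analysis.roi_mean_intensity(np.full(7, 42.0)) == 42.0

    def test_first_middle_last_average(self):
        assert analysis.roi_mean_intensity(np.array([10., 20., 30., 40., 50.])) == 30.0

    def test_image_stack_with_roi(self):
        stack = np.zeros((5, 8, 8))
        stack[:, 2:4, 2:4] = 9.0
        assert analysis.roi_mean_intensity(stack, roi=(2, 2, 2, 2)) == 9.0
        assert analysis.roi_mean_intensity(stack) == pytest.approx(9.0 * 4 / 64)

    def test_roi_out_of_bounds(self):
        with pytest.raises(AnalysisError, match="out of bounds"):
            analysis.roi_mean_intensity(np.zeros((3, 8, 8)), roi=(6, 6, 4, 4))

    def test_empty_stack(self):
        with pytest.raises(AnalysisError):
            analysis.roi_mean_intensity(np.array([]))


class TestCarryoverTable:
    def make_simple(self, buffer_value):
        plate = wf.PlateSpec.custom(1, 3)
        order = wf.snake_order(plate)
        pm = wf.alternating_map(plate, wf.FluidLabel("fluorescein"),
                                wf.FluidLabel("water"), order)
        intensities = {"A1": 1100.0, "A2": buffer_value, "A3": 1100.0}
        return intensities, pm, order

    def test_reference_arithmetic(self):
        # baseline 100, dye 1100, buffer 103.2 -> 0.32%
        intensities, pm, order = self.make_simple(103.2)
        tab = analysis.carryover_table(intensities, pm, order, baseline=100.0)
        assert tab.table["percent"].iloc[0] == pytest.approx(0.32)

    def test_buffer_at_baseline_is_zero(self):
        intensities, pm, order = self.make_simple(100.0)
        tab = analysis.carryover_table(intensities, pm, order, baseline=100.0)
        assert tab.table["percent"].iloc[0] == 0.0

    def test_dead_dye_well_rejected(self):
        intensities, pm, order = self.make_simple(103.2)
        intensities["A1"] = 90.0  # below baseline
        with pytest.raises(AnalysisError, match="A2"):
            analysis.carryover_table(intensities, pm, order, baseline=100.0)

    def test_well_id_baseline_convention(self):
        # buffer-first plate: A1 is the camera-baseline well
        plate = wf.PlateSpec.custom(1, 4)
        order = wf.snake_order(plate)
        pm = wf.alternating_map(plate, wf.FluidLabel("water"),
                                wf.FluidLabel("fluorescein"), order)
        intensities = {"A1": 100.0, "A2": 1100.0, "A3": 103.2, "A4": 1100.0}
        tab = analysis.carryover_table(intensities, pm, order,
                                       baseline=wf.WellId.parse("A1"))
        assert len(tab.table) == 1
        assert tab.table["percent"].iloc[0] == pytest.approx(0.32)

    def test_default_synthetic_scan_recovers_48_switches(self, carryover_scan):
        tab = wf.analyze_carryover_scan(carryover_scan)
        assert len(tab.table) == 48
        assert tab.mean_percent == pytest.approx(0.32, abs=0.03)

    def test_noiseless_scan_recovers_f_exactly(self):
        pm, order = wf.carryover_scenario()
        preset = wf.CarryoverPreset(
            model=wf.CarryoverModel(residual_fraction=0.005, residual_sd=0.0),
            noise_sd=0.0)
        scan = wf.gen_carryover_scan(pm, order, preset, seed=0)
        tab = wf.analyze_carryover_scan(scan)
        assert tab.table["percent"].to_numpy() == pytest.approx(0.5, abs=1e-12)


class TestDff:
    def test_constant_trace_is_zero(self):
        assert analysis.dff(np.full(100, 50.0), 10, 5.0) == pytest.approx(0.0)

    def test_doubling_is_one(self):
        v = np.full(100, 50.0)
        v[60:] = 100.0
        assert analysis.dff(v, 10, 5.0)[60] == pytest.approx(1.0)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(AnalysisError, match="F0"):
            analysis.dff(np.zeros(100), 10, 5.0)

    def test_empty_window_rejected(self):
        with pytest.raises(AnalysisError):
            analysis.dff(np.ones(100), 10, 0.0)

    @given(st.floats(0.01, 1e4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(12)
        v = 100.0 + rng.normal(0, 3, size=200).cumsum() * 0.01 + 100.0
        d1 = analysis.dff(v, 10, 10.0)
        d2 = analysis.dff(scale * v, 10, 10.0)
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestPeakResponse:
    def test_triangular_bump_height(self):
        d = np.zeros(300)
        d[100:121] = np.concatenate([np.linspace(0, 0.8, 11),
                                     np.linspace(0.8, 0, 11)[1:]])
        assert analysis.peak_response(d, 10, 10.0, 5.0) == pytest.approx(0.8)

    def test_window_excludes_late_activity(self):
        d = np.zeros(300)
        d[290] = 5.0  # far outside stim + post window
        assert analysis.peak_response(d, 10, 5.0, 10.0) == 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(AnalysisError):
            analysis.peak_response(np.zeros(10), 10, 5.0, 10.0)


class TestDoseResponseFit:
    @staticmethod
    def hill_peaks(r_max, ec50, hill, concs, n_animals=5, pulses=2):
        rows = [{"conc": c, "animal": a, "pulse": p,
                 "peak": r_max * (c ** hill / (c ** hill + ec50 ** hill) if c else 0.0)}
                for c in concs for a in range(n_animals) for p in range(1, pulses + 1)]
        return pd.DataFrame(rows)

    def test_noiseless_exact_recovery(self):
        concs = [0.0] + [11.5e-9 * 10 ** k for k in range(7)]
        peaks = self.hill_peaks(0.8, 3e-7, 1.7, concs)
        fit = wf.dose_response_fit(peaks)
        assert fit.r_max == pytest.approx(0.8, rel=1e-4)
        assert fit.ec50 == pytest.approx(3e-7, rel=1e-3)
        assert fit.hill == pytest.approx(1.7, rel=1e-3)
        assert fit.bottom == pytest.approx(0.0, abs=1e-4)
        assert not fit.warnings

    def test_monotone_decreasing_data_flagged(self):
        concs = [11.5e-9 * 10 ** k for k in range(7)]
        rows = [{"conc": c, "animal": a, "pulse": 1, "peak": 1.0 / (1 + i)}
                for i, c in enumerate(concs) for a in range(4)]
        fit = wf.dose_response_fit(pd.DataFrame(rows))
        assert fit.warnings  # ec50 out of span / unreliable intervals

    def test_too_few_concentrations_rejected(self):
        peaks = self.hill_peaks(1.0, 1e-6, 1.0, [0.0, 1e-7, 1e-6])
        with pytest.raises(AnalysisError, match="4"):
            wf.dose_response_fit(peaks)

    def test_per_conc_summaries_carry_both_n_conventions(self, dose_response_peaks):
        fit = wf.dose_response_fit(dose_response_peaks, neuron="AWA")
        sat = fit.per_conc[fit.per_conc.conc == 11.5e-3].iloc[0]
        assert sat.n_animals == 18
        assert sat.n_traces == 72
        assert len(fit.poly_coeffs) == 4

    def test_json_export(self, dose_response_peaks, tmp_path):
        fit = wf.dose_response_fit(dose_response_peaks, neuron="AWA")
        fit.to_json(tmp_path / "fit.json")
        import json
        d = json.loads((tmp_path / "fit.json").read_text())
        assert d["ec50"] == pytest.approx(fit.ec50)


class TestOneSampleT:
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=30))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_brute_force_definition(self, xs):
        x = np.asarray(xs)
        if x.std(ddof=1) == 0:
            t, p, n = analysis.one_sample_t(x)
            assert np.isnan(t)
            return
        t, p, n = analysis.one_sample_t(x)
        # brute force from the definition, and scipy as an independent oracle
        t_def = x.mean() * np.sqrt(len(x)) / x.std(ddof=1)
        assert t == pytest.approx(t_def, rel=1e-12)
        t_sp, p_sp = stats.ttest_1samp(x, 0.0)
        assert t == pytest.approx(t_sp, rel=1e-9)
        assert p == pytest.approx(p_sp, rel=1e-9)

    def test_needs_two_observations(self):
        with pytest.raises(AnalysisError):
            analysis.one_sample_t(np.array([1.0]))


class TestScreenStats:
    def small_screen(self, suppression, n_animals=6, noise=0.0, animal_sd=0.0,
                     seed=0):
        solvents = sorted({s for s, _ in suppression})
        preset = wf.ScreenPreset(solvents=tuple(solvents), suppression=suppression,
                                 noise_sd=noise, animal_sd=animal_sd)
        pm, seq = wf.screen_map(solvents, [1.0, 5.0], wf.FluidLabel("buffer"),
                                wf.PlateSpec.from_format("96-medium"))
        ts = wf.gen_screen(preset, n_animals=n_animals, plate_map=pm,
                           sequence=seq, seed=seed)
        return analysis.extract_peaks(ts), pm, seq

    def test_zero_effect_noiseless_nothing_significant(self):
        sup = {(s, c): 1.0 for s in ("a", "b") for c in (1.0, 5.0)}
        peaks, pm, seq = self.small_screen(sup)
        res = wf.screen_stats(peaks, pm, seq)
        assert not res.suppressors()
        assert res.table["degenerate"].all()  # zero-variance differences

    def test_suppressor_detected_with_noise(self):
        sup = {("a", 1.0): 0.3, ("a", 5.0): 0.3, ("b", 1.0): 1.0, ("b", 5.0): 1.0}
        peaks, pm, seq = self.small_screen(sup, n_animals=10, noise=0.05,
                                           animal_sd=0.1)
        res = wf.screen_stats(peaks, pm, seq)
        assert set(res.suppressors()) == {("a", 1.0), ("a", 5.0)}

    def test_missing_prior_control_named(self):
        plate = wf.PlateSpec.custom(1, 4)
        pm = wf.PlateMap(plate)
        seq = wf.snake_order(plate)
        pm.assign(seq[0], wf.FluidLabel("etoh", 5.0))  # solvent first: invalid
        for w in seq[1:]:
            pm.assign(w, wf.FluidLabel("buffer"))
        peaks = pd.DataFrame({"animal": [0, 1] * 4,
                              "well": sum([[str(w)] * 2 for w in seq], []),
                              "peak": 1.0})
        with pytest.raises(AnalysisError, match="A1"):
            wf.screen_stats(peaks, pm, seq)

    def test_bonferroni_m_defaults_to_comparison_count(self, screen_experiment):
        _, pm, seq, peaks = screen_experiment
        res = wf.screen_stats(peaks, pm, seq)
        assert res.m == 28
        assert len(res.table) == 28

    def test_rm_anova_secondary_report(self, screen_experiment):
        _, _, _, peaks = screen_experiment
        f, df1, df2, p = analysis.rm_anova_f(peaks)
        assert f > 1.0 and p < 0.001
        assert df1 == 56 and df2 == 56 * 19


class TestStainingCurve:
    def test_flat_series_reports_no_onset(self, staining_timeline):
        series = wf.gen_staining_timecourse(staining_timeline, plateau=100.0,
                                            background=100.0, noise_sd=1.0, seed=0)
        summary = wf.staining_curve(series, staining_timeline)
        assert summary.onset_lag_min is None

    def test_ten_segments_all_sampled(self, staining_timeline):
        series = wf.gen_staining_timecourse(staining_timeline, seed=0)
        summary = wf.staining_curve(series, staining_timeline)
        assert len(summary.step_means) == 10
        assert (summary.step_means["n_samples"] >= 1).all()

    def test_onset_near_15_minutes(self, staining_timeline):
        series = wf.gen_staining_timecourse(staining_timeline, seed=0)
        summary = wf.staining_curve(series, staining_timeline)
        assert summary.onset_lag_min == pytest.approx(15.0, abs=1.5)

    def test_short_series_rejected(self, staining_timeline):
        series = wf.gen_staining_timecourse(staining_timeline, seed=0).iloc[:40]
        with pytest.raises(AnalysisError, match="final step"):
            wf.staining_curve(series, staining_timeline)
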