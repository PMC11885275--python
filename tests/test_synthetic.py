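"""Generator contracts: determinism, spectral calibration, ground truth."""

import numpy as np
import pytest

from dlsflow.hrv import detect_beats, extract_pulsatile
from dlsflow.hurst import estimate_hurst
from dlsflow.synthetic import (BandFractionSpec, CohortSpec, FlowSignalSpec,
                               ParamDist, fractional_gaussian_noise,
                               lps_study_scenario, simulate_cohort,
                               simulate_fractal_flowmotion,
                               simulate_pulsatile_flow, simulate_speckle_trace)

from _oracles import periodogram_band_powers, rescaled_range_hurst


class TestFractalFlowmotion:
    def test_seed_determinism(self):
        spec = FlowSignalSpec(duration=60.0, hurst_target=0.7, seed=5)
        a = simulate_fractal_flowmotion(spec)
        b = simulate_fractal_flowmotion(spec)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_h_half_is_serially_uncorrelated(self):
        spec = FlowSignalSpec(duration=2 ** 14 / 100.0, hurst_target=0.5, seed=2)
        x = simulate_fractal_flowmotion(spec).samples
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 0.05

    def test_recovers_persistent_target(self):
        ests = [estimate_hurst(simulate_fractal_flowmotion(
            FlowSignalSpec(duration=2 ** 15 / 100.0, hurst_target=0.8, seed=s)))
            for s in range(20)]
        assert abs(np.mean(ests) - 0.80) < 0.05

    def test_agrees_with_rescaled_range_oracle(self):
        rng = np.random.default_rng(3)
        for h in (0.3, 0.6, 0.9):
            x = fractional_gaussian_noise(2 ** 14, h, rng)
            assert abs(rescaled_range_hurst(x) - h) < 0.2

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            FlowSignalSpec(hurst_target=2.5)
        with pytest.raises(ValueError):
            FlowSignalSpec(hurst_target=0.0)


class TestPulsatileFlow:
    def test_beat_count_matches_rate(self):
        spec = FlowSignalSpec(duration=60.0, heart_rate_mean=120,
                              lf_target=0.0, hf_target=0.0, ibi_cv=0.0,
                              amplitude_modulation=0.0, seed=3)
        flow = simulate_pulsatile_flow(spec)
        assert abs(len(flow.meta["beat_times"]) - 120) <= 1
        beats = detect_beats(extract_pulsatile(flow))
        assert abs(beats.n_beats - 120) <= 1

    def test_zero_pulse_amplitude_yields_no_beats(self):
        spec = FlowSignalSpec(duration=120.0, pulsatile_amplitude=0.0, seed=7)
        with pytest.warns(UserWarning):
            beats = detect_beats(extract_pulsatile(simulate_pulsatile_flow(spec)))
        assert beats.n_beats == 0

    def test_lf_hf_targets_rejected_when_inconsistent(self):
        with pytest.raises(ValueError):
            FlowSignalSpec(lf_target=0.7, hf_target=0.5)

    def test_baseline_offset_present(self):
        flow = simulate_pulsatile_flow(FlowSignalSpec(duration=60.0, seed=1))
        assert 9.0 < np.median(flow.samples) < 12.0


class TestSpeckleTrace:
    def test_single_band_trace_has_no_high_frequency_power(self):
        tr = simulate_speckle_trace(BandFractionSpec((1, 0, 0, 0, 0)),
                                    duration=1.0, seed=1)
        bp = periodogram_band_powers(tr.samples, tr.fs,
                                     (0.5, 1000, 2000, 4000, 10000, 15000))
        assert bp[0] / bp.sum() > 0.999

    def test_equal_fractions_give_equal_band_powers(self):
        tr = simulate_speckle_trace(BandFractionSpec((0.2,) * 5),
                                    duration=2.0, seed=2)
        bp = periodogram_band_powers(tr.samples, tr.fs,
                                     (0.5, 1000, 2000, 4000, 10000, 15000))
        np.testing.assert_allclose(bp / bp.sum(), 0.2, atol=0.004)

    def test_random_specs_calibrated_within_two_percent(self, rng):
        edges = (0.5, 1000, 2000, 4000, 10000, 15000)
        for _ in range(10):
            frac = rng.dirichlet(np.ones(5))
            tr = simulate_speckle_trace(BandFractionSpec(tuple(frac)),
                                        duration=10.0,
                                        seed=int(rng.integers(2 ** 31)))
            bp = periodogram_band_powers(tr.samples, tr.fs, edges)
            np.testing.assert_allclose(bp / bp.sum(), frac, atol=0.02)

    def test_sub_nyquist_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_speckle_trace(BandFractionSpec((0.2,) * 5), fs_fast=20_000)


class TestCohort:
    def test_default_study_layout(self):
        recs = simulate_cohort(lps_study_scenario(seed=0))
        assert len(recs) == 30
        groups = {r.group for r in recs}
        assert groups == {"control", "LPS", "resuscitation"}
        assert len(recs[0].flow_specs) == 8        # 2 sites x 4 timepoints

    def test_minimal_cohort(self):
        spec = lps_study_scenario(n_per_group=1, seed=1)
        recs = simulate_cohort(spec)
        assert len(recs) == 3

    def test_cohort_seed_determinism(self):
        a = simulate_cohort(lps_study_scenario(n_per_group=2, seed=9))
        b = simulate_cohort(lps_study_scenario(n_per_group=2, seed=9))
        for ra, rb in zip(a, b):
            assert ra.flow_specs == rb.flow_specs
            assert ra.band_specs == rb.band_specs

    def test_group_medians_match_profiles(self):
        # with many subjects the sample median approaches the profile median
        spec = lps_study_scenario(n_per_group=200, seed=4)
        recs = simulate_cohort(spec)
        vals = [r.ground_truth("peripheral", "T1")["hurst"]
                for r in recs if r.group == "LPS"]
        assert abs(np.median(vals) - 0.64) < 0.06

    def test_param_dist_median_iqr(self, rng):
        d = ParamDist(1.03, 0.96, 1.18)
        draws = d.draw(rng, 20_000)
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        assert abs(med - 1.03) < 0.01
        # symmetric logistic matches the IQR *width* around the median
        assert abs((q3 - q1) - (1.18 - 0.96)) < 0.01

    def test_control_scenario_hurst_stable_over_timepoints(self):
        # constant ground truth across timepoints -> stable windowed medians
        from dlsflow.hurst import windowed_hurst
        meds = {tp: [] for tp in ("T0", "T1", "T2", "T3")}
        for seed in range(5):
            recs = simulate_cohort(lps_study_scenario(
                n_per_group=1, seed=seed, flow_duration=240.0))
            ctrl = next(r for r in recs if r.group == "control")
            for tp in meds:
                flow = ctrl.flow_signal("central", tp)
                meds[tp].append(windowed_hurst(flow).median())
        grand = [np.mean(v) for v in meds.values()]
        assert max(grand) - min(grand) < 0.1
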