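"""Statistical battery against brute-force enumeration and formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlsflow.signals import BloodFlowSeries
from dlsflow.stats import (friedman, kruskal_wallis, pairwise_wilcoxon,
                           run_comparisons, timepoint_median, youden_cutoff)

from _oracles import (exact_rank_sum_p, exact_signed_rank_p, friedman_formula,
                      kruskal_wallis_formula, youden_scan)


class TestTimepointMedian:
    def _series(self, x, fs=1.0, start=0.0):
        return BloodFlowSeries(np.asarray(x, float), fs, start_time=start, kind="TBF")

    def test_constant_window(self):
        assert timepoint_median(self._series(np.full(900, 7.0)), 900.0) == 7.0

    def test_arithmetic_median_of_ramp(self):
        s = self._series(np.arange(1.0, 901.0))
        assert timepoint_median(s, 900.0) == 450.5

    def test_matches_sort_oracle_and_ignores_nan(self, rng):
        x = rng.normal(size=900)
        x[rng.integers(0, 900, 50)] = np.nan
        s = self._series(x)
        expected = np.median(np.sort(x[np.isfinite(x)]))
        assert timepoint_median(s, 900.0) == expected

    def test_empty_window_warns_missing(self):
        with pytest.warns(UserWarning):
            out = timepoint_median(self._series(np.ones(10), start=5000.0), 900.0)
        assert np.isnan(out)


class TestKruskalWallis:
    def test_identical_groups_give_p_one(self):
        res = kruskal_wallis([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_separated_groups_match_formula_oracle(self):
        groups = [[1, 2, 3], [11, 12, 13], [21, 22, 23]]
        res = kruskal_wallis(groups)
        h, p = kruskal_wallis_formula(groups)
        assert res.statistic == pytest.approx(h, abs=1e-9)
        assert res.p_raw == pytest.approx(p, abs=1e-9)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(25):
            groups = [rng.normal(size=int(rng.integers(2, 9))) for _ in range(3)]
            res = kruskal_wallis(groups)
            h, p = kruskal_wallis_formula(groups)
            assert res.statistic == pytest.approx(h, abs=1e-9)
            assert res.p_raw == pytest.approx(p, abs=1e-9)

    def test_label_permutation_leaves_h_distribution_invariant(self, rng):
        # the H statistic is a function of ranks only; permuting group
        # labels resamples from the same null distribution
        pooled = rng.normal(size=9)
        h_ref = sorted(
            kruskal_wallis([p[:3], p[3:6], p[6:]]).statistic
            for p in (rng.permutation(pooled) for _ in range(200)))
        h_new = sorted(
            kruskal_wallis([p[:3], p[3:6], p[6:]]).statistic
            for p in (rng.permutation(pooled) for _ in range(200)))
        assert abs(np.median(h_ref) - np.median(h_new)) < 0.8

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0], [4.0, 5.0]])


class TestPairwiseWilcoxon:
    def test_rank_sum_matches_exhaustive_enumeration(self):
        x, y = list(range(1, 11)), list(range(11, 21))
        res = pairwise_wilcoxon([x, y])[0]
        assert res.p_raw == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    def test_random_rank_sum_instances_match_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 9)))
            y = rng.normal(size=int(rng.integers(3, 9)))
            res = pairwise_wilcoxon([x, y])[0]
            assert res.p_raw == pytest.approx(exact_rank_sum_p(x, y), abs=1e-9)

    def test_random_signed_rank_instances_match_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 9))
            x, y = rng.normal(size=n), rng.normal(size=n)
            res = pairwise_wilcoxon([x, y], paired=True)[0]
            assert res.p_raw == pytest.approx(exact_signed_rank_p(x, y), abs=1e-9)

    def test_identical_paired_vectors_give_p_one(self):
        res = pairwise_wilcoxon([[1, 2, 3, 4], [1, 2, 3, 4]], paired=True)[0]
        assert res.p_raw == 1.0

    def test_bonferroni_multiplier_counts_contrasts(self):
        groups = [np.arange(5) + 10 * i for i in range(3)]
        results = pairwise_wilcoxon(groups)
        assert len(results) == 3
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 3))
            assert res.p_adjusted >= res.p_raw

    def test_unequal_paired_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon([[1, 2, 3], [1, 2]], paired=True)


class TestFriedman:
    def test_identical_columns_give_p_one(self):
        m = np.tile([3.0, 5.0, 1.0, 2.0], (4, 1)).T
        res = friedman(m)
        assert res.p_raw == 1.0

    def test_strictly_increasing_rows_reach_closed_form_maximum(self):
        n, k = 10, 4
        m = np.tile(np.arange(k, dtype=float), (n, 1)) + \
            np.arange(n, dtype=float)[:, None] * 100
        res = friedman(m)
        assert res.statistic == pytest.approx(n * (k - 1), abs=1e-9)

    def test_random_instances_match_formula_oracle(self, rng):
        for _ in range(20):
            m = rng.normal(size=(int(rng.integers(3, 8)), int(rng.integers(3, 6))))
            res = friedman(m)
            q, p = friedman_formula(m)
            assert res.statistic == pytest.approx(q, abs=1e-9)
            assert res.p_raw == pytest.approx(p, abs=1e-9)

    def test_column_permutation_leaves_statistic_distribution_invariant(self, rng):
        m = rng.normal(size=(6, 4))
        stats = [friedman(m[:, rng.permutation(4)]).statistic for _ in range(100)]
        assert np.min(stats) >= 0

    def test_missing_cells_rejected(self):
        m = np.ones((4, 4))
        m[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman(m)


class TestYoudenCutoff:
    def test_fully_separated_groups(self):
        values = np.r_[np.linspace(0.1, 0.4, 10), np.linspace(0.9, 1.2, 10)]
        labels = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        res = youden_cutoff(values, labels)
        assert res.sensitivity == 100.0 and res.specificity == 100.0
        assert res.youden == pytest.approx(1.0)
        assert 0.4 < res.cutoff < 0.9

    def test_identical_distributions_give_zero_youden(self):
        values = np.r_[np.arange(8.0), np.arange(8.0) + 1e-9]
        labels = np.r_[np.ones(8), np.zeros(8)].astype(bool)
        res = youden_cutoff(values, labels)
        assert res.youden == pytest.approx(0.0, abs=1e-6)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_exhaustive_scan_oracle(self, seed):
        r = np.random.default_rng(seed)
        n_pos, n_neg = int(r.integers(3, 12)), int(r.integers(3, 12))
        values = np.r_[r.normal(0, 1, n_pos), r.normal(1, 1, n_neg)]
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(bool)
        res = youden_cutoff(values, labels)
        cut, sens, spec, j = youden_scan(values, labels)
        assert res.cutoff == pytest.approx(cut, abs=1e-12)
        assert res.sensitivity == pytest.approx(sens, abs=1e-9)
        assert res.specificity == pytest.approx(spec, abs=1e-9)
        assert res.youden == pytest.approx(j, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff([1.0, 2.0], [True, True])


def _make_table(rng, n=10, params=("hurst_full",), delta=0.0):
    rows = []
    for g_i, group in enumerate(("control", "LPS", "resuscitation")):
        for s in range(n):
            for site in ("central", "peripheral"):
                for tp in ("T0", "T1", "T2", "T3"):
                    for p in params:
                        shift = delta if (group != "control" and tp in ("T2", "T3")) else 0.0
                        rows.append(dict(subject_id=f"{group}_{s}", group=group,
                                         site=site, timepoint=tp, parameter=p,
                                         value=rng.normal() - shift))
    return pd.DataFrame(rows)


class TestRunComparisons:
    def test_single_cell_plan_yields_one_omnibus_row(self, rng):
        table = _make_table(rng)
        sub = table[(table.timepoint == "T0") & (table.site == "central")]
        res = run_comparisons(sub.copy())
        omni = res["between_groups"]
        assert (omni.contrast == "omnibus").sum() == 1

    def test_pairwise_rows_only_after_significant_omnibus(self, rng):
        table = _make_table(rng, delta=3.0)
        res = run_comparisons(table)
        bg = res["between_groups"]
        for (_, _, tp), sub in bg.groupby(["parameter", "site", "timepoint"]):
            omni_p = sub.loc[sub.contrast == "omnibus", "p_raw"].iloc[0]
            n_pairwise = (sub.contrast != "omnibus").sum()
            assert (n_pairwise == 3) == (omni_p < 0.05)

    def test_effect_detected_where_injected(self, rng):
        table = _make_table(rng, delta=3.0)
        res = run_comparisons(table)
        bg = res["between_groups"]
        omni = bg[bg.contrast == "omnibus"].set_index("timepoint")
        assert (omni.loc["T2", "p_raw"] < 0.05).all()
        y = res["youden"].set_index("timepoint")
        assert (y.loc["T2", "youden"] > 0.5).all()

    def test_one_subject_per_group_rejected(self, rng):
        table = _make_table(rng, n=1)
        with pytest.raises(ValueError, match="n >= 2"):
            run_comparisons(table)

    def test_duplicate_rows_rejected(self, rng):
        table = _make_table(rng)
        with pytest.raises(ValueError, match="duplicate"):
            run_comparisons(pd.concat([table, table.iloc[:5]]))


class TestStudyScenarioPattern:
    def test_hurst_group_differences_appear_peripherally_first(self):
        """Endotoxin-scenario cohorts flag group differences in the Hurst
        exponent at T2 on both sites but at T1 only peripherally, the
        modal outcome over replicate cohorts."""
        from dlsflow.hurst import windowed_hurst
        from dlsflow.synthetic import lps_study_scenario, simulate_cohort

        patterns = []
        for seed in range(3):
            recs = simulate_cohort(lps_study_scenario(
                n_per_group=10, seed=seed, flow_duration=240.0))
            rows = []
            for r in recs:
                for site in ("central", "peripheral"):
                    for tp in ("T1", "T2"):
                        rows.append(dict(
                            subject_id=r.subject_id, group=r.group, site=site,
                            timepoint=tp, parameter="hurst_full",
                            value=windowed_hurst(r.flow_signal(site, tp)).median()))
            res = run_comparisons(pd.DataFrame(rows))
            omni = res["between_groups"]
            omni = omni[omni.contrast == "omnibus"].set_index(["site", "timepoint"])
            sig = omni["p_raw"] < 0.05
            patterns.append((bool(sig.loc[("central", "T2")]),
                             bool(sig.loc[("peripheral", "T2")]),
                             bool(sig.loc[("peripheral", "T1")]),
                             bool(sig.loc[("central", "T1")])))
        modal = max(set(patterns), key=patterns.count)
        assert modal == (True, True, True, False)
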