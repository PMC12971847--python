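"""Outlier screening, rank tests, post hoc comparisons and power simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from suturemetrics import (
    ConfigError,
    InputError,
    compare_groups,
    describe_by,
    dunn_posthoc,
    iqr_outlier_filter,
    kruskal_wallis,
    required_n_simulation,
    validate_cohort_frame,
)
from oracles import dunn_z, kruskal_h


class TestIqrFilter:
    def test_single_extreme_removed(self):
        kept, removed = iqr_outlier_filter([1, 2, 3, 4, 100])
        assert kept.tolist() == [1, 2, 3, 4]
        assert removed == [4]

    def test_constant_data_untouched(self):
        kept, removed = iqr_outlier_filter([5, 5, 5, 5, 5])
        assert len(kept) == 5 and removed == []

    def test_gaussian_removal_rate_near_tukey_theory(self, rng):
        """k=1.5 fences clip ~0.7% of a standard normal."""
        rates = []
        for _ in range(50):
            x = rng.normal(size=1000)
            _, removed = iqr_outlier_filter(x)
            rates.append(len(removed) / 1000)
        assert 0.003 <= np.mean(rates) <= 0.014

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=40))
    def test_output_is_subsequence_and_infence_data_survive(self, xs):
        kept, removed = iqr_outlier_filter(xs)
        remaining = list(xs)
        for v in kept:  # subsequence check
            assert v in remaining
            remaining.remove(v)
        q1, q3 = np.percentile(xs, [25, 75])
        if max(xs) <= q3 + 1.5 * (q3 - q1) and min(xs) >= q1 - 1.5 * (q3 - q1):
            assert removed == []

    def test_too_few_values_refused(self):
        with pytest.raises(InputError):
            iqr_outlier_filter([1, 2, 3])


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_h(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)

    def test_matches_textbook_implementation_with_ties(self, rng):
        for _ in range(20):
            groups = [rng.integers(0, 6, size=rng.integers(3, 9)).tolist()
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            h, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kruskal_h(groups), abs=1e-10)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 1, 2)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            kruskal_wallis([[1], [2, 3]])


class TestDunn:
    def test_identical_groups_all_p_one(self):
        for adj in ("none", "bonferroni", "holm"):
            p = dunn_posthoc([[1, 2, 3]] * 3, adjustment=adj)
            assert np.allclose(p, 1.0)

    def test_extreme_pair_attains_minimum_p(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(2, 1, 10), rng.normal(6, 1, 10)]
        p = dunn_posthoc(groups)
        iu = np.triu_indices(3, 1)
        assert p[0, 2] == min(p[iu])

    def test_z_matches_brute_force(self, rng):
        from scipy.stats import norm
        groups = [rng.integers(0, 10, 6).tolist() for _ in range(3)]
        p = dunn_posthoc(groups)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            want = 2 * norm.sf(abs(dunn_z(groups, i, j)))
            assert p[i, j] == pytest.approx(min(want, 1.0), abs=1e-10)

    def test_bonferroni_is_three_times_raw(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1)]
        raw = dunn_posthoc(groups, "none")
        bonf = dunn_posthoc(groups, "bonferroni")
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(bonf[iu], np.minimum(1.0, 3 * raw[iu]))

    def test_adjusted_never_below_raw(self, rng):
        groups = [rng.normal(m, 1, 7) for m in (0, 1, 3)]
        raw = dunn_posthoc(groups, "none")
        for adj in ("bonferroni", "holm"):
            assert (dunn_posthoc(groups, adj) >= raw - 1e-15).all()

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ConfigError):
            dunn_posthoc([[1, 2], [3, 4]], adjustment="sidak")


class TestRequiredN:
    def test_null_configuration_hits_sentinel(self):
        est = required_n_simulation([10.0, 10.0], [2.0, 2.0], test="ttest",
                                    n_sims=400, seed=3, n_max=40)
        assert est.required_n_per_group is None
        assert all(p < 0.25 for p in est.power_curve.values())

    def test_effect_monotonicity(self):
        """A larger mean separation never needs more samples."""
        prev = np.inf
        for d in (0.6, 1.0, 1.6):
            est = required_n_simulation([0.0, d], [1.0, 1.0], test="ttest",
                                        n_sims=3000, seed=11, n_max=200)
            assert est.required_n_per_group is not None
            assert est.required_n_per_group <= prev + 1  # +1: Monte-Carlo slack
            prev = est.required_n_per_group

    def test_anova_and_kruskal_agree_roughly(self):
        kw = required_n_simulation([0, 1], [1, 1], test="kruskal", n_sims=600,
                                   seed=5, n_max=60)
        an = required_n_simulation([0, 1], [1, 1], test="anova", n_sims=600,
                                   seed=5, n_max=60)
        assert abs(kw.required_n_per_group - an.required_n_per_group) <= 4

    def test_doubling_nsims_is_within_mc_error(self):
        a = required_n_simulation([0, 1], [1, 1], test="ttest", n_sims=2000,
                                  seed=2, n_max=60, observed_n=17)
        b = required_n_simulation([0, 1], [1, 1], test="ttest", n_sims=4000,
                                  seed=9, n_max=60, observed_n=17)
        se = np.sqrt(0.8 * 0.2 / 2000) + np.sqrt(0.8 * 0.2 / 4000)
        assert abs(a.achieved_power - b.achieved_power) < 4 * se

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            required_n_simulation([0.0], [1.0])
        with pytest.raises(InputError):
            required_n_simulation([0, 1], [1, 0])
        with pytest.raises(ConfigError):
            required_n_simulation([0, 1], [1, 1], test="wilcoxon")


def toy_frame():
    rows = []
    rng = np.random.default_rng(0)
    for d, dev in enumerate(("laparoscopy", "dvrk", "flex")):
        for e, exp in enumerate(("beginner", "advanced", "master")):
            for i in range(5):
                rows.append({
                    "trial_id": f"{dev}_{exp}_{i}", "operator_id": f"op{e}{i}",
                    "device": dev, "experience": exp,
                    "burst_pressure_mmHg": 15 + d - e + rng.normal(0, 2),
                    "time_s": 1500 + 400 * d + rng.normal(0, 100),
                })
    return pd.DataFrame(rows)


class TestDescribeAndCompare:
    def test_single_record_stratum_has_no_sd(self):
        df = toy_frame().groupby("device", as_index=False).head(1)
        out = describe_by(df, "device", "burst_pressure_mmHg")
        assert out["sd"].isna().all()
        assert (out["n"] == 1).all()

    def test_full_crossing_yields_nine_strata_of_five(self):
        out = describe_by(toy_frame(), ["device", "experience"], "burst_pressure_mmHg")
        assert len(out) == 9
        assert (out["n"] == 5).all()

    def test_compare_groups_reports_screening(self):
        df = toy_frame()
        df.loc[0, "burst_pressure_mmHg"] = 500.0  # plant one gross outlier
        comp = compare_groups(df, "burst_pressure_mmHg", "device")
        assert comp.outliers_removed == [df.loc[0, "trial_id"]]
        assert sum(comp.n_per_group.values()) == len(df) - 1
        assert 0 <= comp.p_value <= 1
        assert np.allclose(np.diag(comp.posthoc), 1.0)

    def test_vocabulary_violations_listed(self):
        df = toy_frame()
        df.loc[0, "device"] = "robot9000"
        with pytest.raises(InputError, match="robot9000"):
            validate_cohort_frame(df)

    def test_missing_column_reported(self):
        with pytest.raises(InputError, match="time_s"):
            validate_cohort_frame(toy_frame().drop(columns=["time_s"]))
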