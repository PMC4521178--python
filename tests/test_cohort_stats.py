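import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import glycurve as gc
from glycurve.cohort_stats import bonferroni, rm_anova_interaction


def oneway_f_by_sums_of_squares(samples):
    """Independent oracle: one-way ANOVA F from explicit sums of squares."""
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ssb = sum(len(s) * (np.mean(s) - grand) ** 2 for s in samples)
    ssw = sum(((np.asarray(s) - np.mean(s)) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = len(all_vals) - len(samples)
    return (ssb / df_b) / (ssw / df_w), df_b, df_w


class TestAncovaGroupTest:
    def test_identical_groups_give_null_f(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        g = ["a"] * 3 + ["b"] * 3
        comp = gc.ancova_group_test(y, g, covariate=[20, 30, 25, 20, 30, 25])
        assert comp.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert comp.p_value == pytest.approx(1.0, abs=1e-10)

    def test_toy_design_matches_hand_computed_sums_of_squares(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5 (df 1), SSW = 4 (df 4) -> F = 13.5
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        g = ["a"] * 3 + ["b"] * 3
        comp = gc.ancova_group_test(y, g, covariate=[1.0] * 6)
        f_oracle, df_b, df_w = oneway_f_by_sums_of_squares([[1, 2, 3], [4, 5, 6]])
        assert f_oracle == pytest.approx(13.5)
        assert (comp.df_num, comp.df_den) == (df_b, df_w)
        assert comp.f_statistic == pytest.approx(f_oracle, rel=1e-10)

    def test_constant_covariate_reduces_to_oneway_anova(self):
        rng = np.random.default_rng(17)
        samples = [rng.normal(m, 1.0, n) for m, n in [(0, 8), (0.7, 11), (0.2, 9)]]
        y = np.concatenate(samples)
        g = np.repeat(["a", "b", "c"], [8, 11, 9])
        comp = gc.ancova_group_test(y, g, covariate=np.full(28, 5.0))
        f_oracle, _, _ = oneway_f_by_sums_of_squares(samples)
        assert comp.f_statistic == pytest.approx(f_oracle, rel=1e-10)
        # scipy as a second, library-independent cross-check
        assert comp.f_statistic == pytest.approx(sps.f_oneway(*samples).statistic, rel=1e-10)
        assert comp.covariates == ()

    def test_covariate_adjustment_changes_the_test(self):
        rng = np.random.default_rng(23)
        age = np.concatenate([rng.normal(30, 3, 15), rng.normal(24, 3, 15)])
        y = 0.5 * age + rng.normal(0, 1.0, 30)  # group difference only via age
        g = np.repeat(["a", "b"], 15)
        raw = gc.ancova_group_test(y, g)
        adj = gc.ancova_group_test(y, g, covariate=age)
        assert adj.p_value > raw.p_value  # adjustment absorbs the age confound
        assert adj.covariates == ("age",)
        # adjusted means are evaluated at the grand covariate mean
        assert abs(adj.adjusted_means["a"] - adj.adjusted_means["b"]) < abs(
            raw.adjusted_means["a"] - raw.adjusted_means["b"]
        )

    def test_pairwise_bonferroni_over_three_groups(self):
        rng = np.random.default_rng(29)
        y = np.concatenate([rng.normal(m, 1, 10) for m in (0, 0, 3)])
        g = np.repeat(["a", "b", "c"], 10)
        comp = gc.ancova_group_test(y, g, covariate=rng.normal(25, 3, 30))
        assert len(comp.pairwise) == 3
        for _, row in comp.pairwise.iterrows():
            assert row["bonferroni_p"] == pytest.approx(
                min(1.0, row["raw_p"] * 3), rel=1e-12
            )
        strong = comp.pairwise.set_index(["group1", "group2"])
        assert strong.loc[("a", "c"), "bonferroni_p"] < 0.05
        assert strong.loc[("a", "b"), "bonferroni_p"] > 0.05

    def test_error_contracts(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            gc.ancova_group_test([1.0, 2.0, 3.0], ["a", "a", "b"])
        with pytest.raises(ValueError, match="constant outcome"):
            gc.ancova_group_test([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="2 groups"):
            gc.ancova_group_test([1.0, 2.0], ["a", "a"])


class TestBonferroni:
    def test_monotone_and_capped(self):
        ps = np.linspace(0.001, 0.9, 30)
        adj = [bonferroni(p, 6) for p in ps]
        assert all(b <= 1.0 for b in adj)
        assert all(x <= y for x, y in zip(adj, adj[1:]))
        assert bonferroni(0.5, 4) == 1.0


class TestRmAnova:
    def test_flat_curves_carry_no_evidence(self):
        Y = np.tile([3.0, 3.0, 3.0], (8, 1))
        res = rm_anova_interaction(Y, ["a"] * 4 + ["b"] * 4)
        assert res.time_F == 0.0
        assert res.interaction_F == 0.0
        assert res.group_F == 0.0

    def test_2x2_interaction_equals_squared_t_on_differences(self):
        rng = np.random.default_rng(41)
        Y = rng.normal(0, 1, (14, 2))
        Y[7:, 1] += 1.2
        g = ["a"] * 7 + ["b"] * 7
        res = rm_anova_interaction(Y, g)
        d = Y[:, 1] - Y[:, 0]
        t = sps.ttest_ind(d[:7], d[7:])
        assert res.interaction_F == pytest.approx(t.statistic**2, rel=1e-8)
        assert res.interaction_p == pytest.approx(t.pvalue, rel=1e-8)
        assert res.gg_epsilon == 1.0  # two timepoints: sphericity is trivial

    def test_sums_of_squares_partition_closes(self):
        rng = np.random.default_rng(43)
        Y = rng.normal(0, 1, (20, 5)) + rng.normal(0, 1, (20, 1))
        g = ["a"] * 6 + ["b"] * 7 + ["c"] * 7
        res = rm_anova_interaction(Y, g)
        parts = (res.ss["group"] + res.ss["subjects_within_groups"] + res.ss["time"]
                 + res.ss["interaction"] + res.ss["error"])
        assert parts == pytest.approx(res.ss["total"], rel=1e-8)

    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(47)
        n = (9, 12, 8)
        Y = np.vstack([
            rng.normal(0, 1, (n[0], 4)) + [0, 1, 2, 1],
            rng.normal(0, 1, (n[1], 4)) + [0, 2, 1, 0.5],
            rng.normal(0, 1.2, (n[2], 4)),
        ])
        g = np.repeat(["a", "b", "c"], n)
        res = rm_anova_interaction(Y, g)
        long = pd.DataFrame({
            "y": Y.ravel(),
            "time": np.tile(np.arange(4), Y.shape[0]),
            "subj": np.repeat(np.arange(Y.shape[0]), 4),
            "group": np.repeat(g, 4),
        })
        aov = pg.mixed_anova(long, dv="y", within="time", between="group",
                             subject="subj").set_index("Source")
        assert res.group_F == pytest.approx(aov.loc["group", "F"], rel=1e-10)
        assert res.time_F == pytest.approx(aov.loc["time", "F"], rel=1e-10)
        assert res.interaction_F == pytest.approx(aov.loc["Interaction", "F"], rel=1e-10)

    def test_epsilon_bounds_and_correction_direction(self):
        rng = np.random.default_rng(53)
        T = 5
        base = rng.normal(0, 1, (30, 1))
        # non-spherical noise plus a real time effect, so F > 1 and the
        # df correction acts in the conservative direction
        Y = base + [0.0, 1.0, 2.0, 1.0, 0.5] + rng.normal(0, [0.2, 0.5, 1.0, 2.0, 4.0], (30, T))
        g = ["a"] * 15 + ["b"] * 15
        res = rm_anova_interaction(Y, g)
        assert 1.0 / (T - 1) <= res.gg_epsilon <= 1.0
        assert res.time_p_gg >= res.time_p  # fewer df -> less significant

    def test_covariate_enters_between_stratum(self):
        rng = np.random.default_rng(59)
        Y = rng.normal(0, 1, (24, 4)) + rng.normal(0, 1, (24, 1))
        g = ["a"] * 12 + ["b"] * 12
        age = rng.normal(25, 3, 24)
        res = rm_anova_interaction(Y, g, covariate=age)
        assert res.group_F_adjusted is not None
        assert res.covariate == "age"
        # the within-subject tests are unchanged by a time-constant covariate
        un = rm_anova_interaction(Y, g)
        assert res.interaction_F == pytest.approx(un.interaction_F, rel=1e-12)

    def test_power_for_builtin_group_time_effect(self):
        """Amplified excursions in one group are detected by the interaction."""
        rng = np.random.default_rng(61)
        kernel = np.array([0.0, 0.87, 0.91, 0.54, 0.25, 0.0])
        n = (14, 21, 24)
        hits = 0
        reps = 50
        for _ in range(reps):
            rows, groups = [], []
            for gi, (label, amp) in enumerate(zip("abc", (1.0, 1.6, 1.0))):
                for _ in range(n[gi]):
                    a = amp * rng.lognormal(np.log(2.0), 0.3)
                    rows.append(a * kernel + rng.normal(0, 0.35, 6))
                    groups.append(label)
            res = rm_anova_interaction(np.vstack(rows), groups)
            hits += res.interaction_p < 0.05
        assert hits / reps >= 0.8

    def test_missing_cell_instructs_exclusion(self):
        Y = np.ones((6, 3))
        Y[2, 1] = np.nan
        with pytest.raises(ValueError, match="exclude"):
            rm_anova_interaction(Y, ["a"] * 3 + ["b"] * 3)


class TestBootstrapGroupDi:
    @staticmethod
    def panels(values_by_group):
        rows = [
            {"group": g, "oral_di": v}
            for g, vals in values_by_group.items()
            for v in vals
        ]
        return pd.DataFrame(rows)

    def test_identical_subjects_give_zero_width(self):
        df = self.panels({"a": [5.0] * 12})
        out = gc.bootstrap_group_di(df, n_boot=200, seed=1)
        assert out.loc[0, "ci_low"] == out.loc[0, "ci_high"] == 5.0

    def test_same_seed_reproduces_ci(self):
        rng = np.random.default_rng(3)
        df = self.panels({"a": rng.lognormal(2, 0.4, 15), "b": rng.lognormal(2.2, 0.4, 20)})
        a = gc.bootstrap_group_di(df, n_boot=500, seed=42)
        b = gc.bootstrap_group_di(df, n_boot=500, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = gc.bootstrap_group_di(df, n_boot=500, seed=43)
        assert not a.equals(c)

    def test_singleton_group_warns_with_nan_ci(self):
        df = self.panels({"a": [4.0, 5.0, 6.0], "b": [7.0]})
        with pytest.warns(UserWarning, match="CI undefined"):
            out = gc.bootstrap_group_di(df, n_boot=200, seed=0)
        row = out.set_index("group").loc["b"]
        assert np.isnan(row["ci_low"]) and np.isnan(row["ci_high"])

    def test_coverage_near_nominal(self):
        """Percentile CI covers the true mean ~95% of the time."""
        rng = np.random.default_rng(71)
        mu_log, sd_log, n = 2.5, 0.3, 25
        true_mean = np.exp(mu_log + sd_log**2 / 2)
        covered = 0
        reps = 200
        for r in range(reps):
            df = self.panels({"a": rng.lognormal(mu_log, sd_log, n)})
            out = gc.bootstrap_group_di(df, n_boot=400, seed=r)
            covered += out.loc[0, "ci_low"] <= true_mean <= out.loc[0, "ci_high"]
        assert 0.88 <= covered / reps <= 0.99

    def test_nboot_floor(self):
        with pytest.raises(ValueError, match="n_boot"):
            gc.bootstrap_group_di(self.panels({"a": [1.0, 2.0]}), n_boot=10, seed=0)
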