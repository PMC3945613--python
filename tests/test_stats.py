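"""Tests for the repeated-measures ANOVA / Dunnett / permutation machinery.

Oracles: an independent brute-force sum-of-squares decomposition coded
here, pingouin's ANOVA implementations, scipy's t distribution, analytic
reductions (F = t^2 for two levels; Dunnett k=1 = paired t), and a
bivariate-normal rectangle probability for the equicorrelated max-|T|
tail.
"""

import numpy as np
import pytest
from scipy import stats as sps

from midlink.stats import (
    dunnett,
    dunnett_maxt_sf,
    permutation_p,
    rm_anova_mixed,
    rm_anova_oneway,
)


def brute_force_oneway_ss(a):
    """Independent SS decomposition by direct summation over cells."""
    s, c = a.shape
    grand = a.sum() / (s * c)
    ss_cond = sum(s * (a[:, j].mean() - grand) ** 2 for j in range(c))
    ss_subj = sum(c * (a[i, :].mean() - grand) ** 2 for i in range(s))
    ss_resid = sum(
        (a[i, j] - a[i, :].mean() - a[:, j].mean() + grand) ** 2
        for i in range(s)
        for j in range(c)
    )
    return ss_cond, ss_subj, ss_resid


class TestOnewayRm:
    def test_identical_responses_give_f_zero_p_one(self):
        out = rm_anova_oneway(np.full((4, 3), 7.0))
        eff = out.effect("condition")
        assert eff.F == 0.0 and eff.p == 1.0

    def test_matches_brute_force_ss_decomposition(self):
        rng = np.random.default_rng(42)
        a = rng.normal(2.0, 1.0, size=(4, 3))
        ss_cond, ss_subj, ss_resid = brute_force_oneway_ss(a)
        out = rm_anova_oneway(a)
        eff = out.effect("condition")
        assert eff.ss == pytest.approx(ss_cond, rel=1e-10)
        assert out.error_strata["subject"][0] == pytest.approx(ss_subj, rel=1e-10)
        assert out.error_strata["residual"][0] == pytest.approx(ss_resid, rel=1e-10)
        F = (ss_cond / 2) / (ss_resid / 6)
        assert eff.F == pytest.approx(F, rel=1e-10)
        assert eff.p == pytest.approx(float(sps.f.sf(F, 2, 6)), rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 4))
        long = pd.DataFrame(
            {
                "y": a.ravel(),
                "subject": np.repeat(np.arange(6), 4),
                "cond": np.tile(np.arange(4), 6),
            }
        )
        pg = pingouin.rm_anova(data=long, dv="y", within="cond", subject="subject")
        pcol = "p_unc" if "p_unc" in pg.columns else "p-unc"
        eff = rm_anova_oneway(a).effect("condition")
        assert eff.F == pytest.approx(float(pg["F"].iloc[0]), rel=1e-8)
        assert eff.p == pytest.approx(float(pg[pcol].iloc[0]), rel=1e-6)

    def test_two_conditions_reduce_to_paired_t_squared(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(9, 2))
        eff = rm_anova_oneway(a).effect("condition")
        t = sps.ttest_rel(a[:, 0], a[:, 1])
        assert eff.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert eff.p == pytest.approx(t.pvalue, rel=1e-8)

    def test_ss_components_sum_to_total(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(7, 5))
        out = rm_anova_oneway(a)
        total = ((a - a.mean()) ** 2).sum()
        parts = out.effect("condition").ss + sum(s for s, _ in out.error_strata.values())
        assert parts == pytest.approx(total, rel=1e-10)

    @pytest.mark.parametrize("shape", [(1, 3), (4, 1)])
    def test_degenerate_designs_rejected(self, shape):
        with pytest.raises(ValueError):
            rm_anova_oneway(np.zeros(shape))

    def test_p_stays_positive_for_extreme_effects(self):
        # enormous F must not underflow p to 0: p is in (0, 1]
        a = np.tile([0.0, 1e6], (8, 1)) + np.random.default_rng(0).normal(size=(8, 2)) * 1e-6
        eff = rm_anova_oneway(a).effect("condition")
        assert 0.0 < eff.p <= 1.0

    def test_missing_cell_rejected(self):
        a = np.ones((4, 3))
        a[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_oneway(a)


class TestMixedRm:
    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        groups = {g: rng.normal(size=(5, 4)) for g in ("a", "b", "c")}
        rows = []
        sid = 0
        for g, mat in groups.items():
            for row in mat:
                for t, y in enumerate(row):
                    rows.append({"y": y, "genotype": g, "time": t, "subject": sid})
                sid += 1
        pg = pingouin.mixed_anova(
            data=pd.DataFrame(rows), dv="y", within="time", between="genotype", subject="subject"
        ).set_index("Source")
        out = rm_anova_mixed(groups)
        assert out.effect("group").F == pytest.approx(float(pg.loc["genotype", "F"]), rel=1e-8)
        assert out.effect("within").F == pytest.approx(float(pg.loc["time", "F"]), rel=1e-8)
        assert out.effect("group_x_within").F == pytest.approx(
            float(pg.loc["Interaction", "F"]), rel=1e-8
        )

    def test_two_group_effect_is_two_sample_t_squared_on_subject_means(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(size=(8, 6)), "b": rng.normal(0.5, 1.0, size=(8, 6))}
        out = rm_anova_mixed(groups)
        t = sps.ttest_ind(groups["a"].mean(axis=1), groups["b"].mean(axis=1))
        assert out.effect("group").F == pytest.approx(t.statistic**2, rel=1e-10)
        assert out.effect("group").p == pytest.approx(t.pvalue, rel=1e-8)

    def test_single_within_level_rejected(self):
        with pytest.raises(ValueError, match="within"):
            rm_anova_mixed({"a": np.ones((3, 1)), "b": np.ones((3, 1))})

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="[Uu]nbalanced"):
            rm_anova_mixed({"a": np.ones((3, 4)), "b": np.ones((5, 4))})

    def test_ss_decomposition_complete(self):
        rng = np.random.default_rng(9)
        groups = {g: rng.normal(size=(4, 5)) for g in "abc"}
        out = rm_anova_mixed(groups)
        stack = np.stack(list(groups.values()))
        total = ((stack - stack.mean()) ** 2).sum()
        parts = sum(e.ss for e in out.effects) + sum(s for s, _ in out.error_strata.values())
        assert parts == pytest.approx(total, rel=1e-8)


class TestDunnett:
    def test_k1_equals_paired_t(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(10, 2))
        a[:, 1] += 0.7
        rep = dunnett(a, ["ctrl", "trt"], "ctrl", n_mc=100_000, seed=3)
        t = sps.ttest_rel(a[:, 1], a[:, 0])
        assert abs(rep.comparisons[0].p_adjusted - t.pvalue) < 0.005

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            a = rng.normal(size=(6, 4))
            rep = dunnett(a, list("cxyz"), "c", n_mc=5000, seed=i)
            for comp in rep.comparisons:
                assert comp.p_adjusted >= comp.p_raw

    def test_equicorrelated_tail_matches_bivariate_normal(self):
        # k = 2, df -> inf: P(max |T| >= c) from an independent
        # bivariate-normal rectangle probability at rho = 0.5
        c = 2.0
        rho = 0.5
        cov = [[1.0, rho], [rho, 1.0]]
        mvn = sps.multivariate_normal(mean=[0, 0], cov=cov)
        inside = (
            mvn.cdf([c, c]) - mvn.cdf([c, -c]) - mvn.cdf([-c, c]) + mvn.cdf([-c, -c])
        )
        expected = 1.0 - inside
        got = dunnett_maxt_sf(np.array([c]), k=2, df=100_000, n_mc=400_000, seed=1)[0]
        assert got == pytest.approx(expected, abs=0.005)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            dunnett(np.ones((4, 3)), list("abc"), "zzz")

    def test_mean_differences_reported(self):
        a = np.array([[1.0, 2.0, 4.0]] * 5) + np.arange(5)[:, None]
        rep = dunnett(a, ["c", "t1", "t2"], "c", n_mc=2000, seed=0)
        assert rep.comparisons[0].mean_diff == pytest.approx(1.0)
        assert rep.comparisons[1].mean_diff == pytest.approx(3.0)


class TestPermutationP:
    def test_observed_above_all_draws(self):
        assert permutation_p(1000.0, np.arange(999), "greater") == pytest.approx(1 / 1000)

    def test_observed_at_median(self):
        null = np.arange(999)
        assert permutation_p(499.0, null, "greater") == pytest.approx(0.5, abs=0.01)

    def test_two_sided_caps_at_one(self):
        assert permutation_p(0.5, np.array([0.0, 1.0, 0.5]), "two-sided") == 1.0

    def test_bounds_and_tie_conservatism(self):
        rng = np.random.default_rng(12)
        null = rng.normal(size=200)
        for obs in [-5.0, 0.0, 5.0, float(null[0])]:
            p = permutation_p(obs, null, "greater")
            assert 1 / 201 <= p <= 1.0
        # a tie counts toward the null
        assert permutation_p(float(null.max()), null, "greater") >= 2 / 201

    def test_add_one_estimator_uniform_on_grid(self):
        # with a continuous null, p takes each grid value 1/(n+1) .. 1
        # equally often: check exact discrete uniformity by rank argument
        rng = np.random.default_rng(13)
        n = 99
        ps = []
        for _ in range(500):
            draws = rng.normal(size=n + 1)
            ps.append(permutation_p(draws[0], draws[1:], "greater"))
        ps = np.array(ps)
        grid = np.arange(1, n + 2) / (n + 1)
        assert set(np.round(ps, 10)).issubset(set(np.round(grid, 10)))
        assert abs(ps.mean() - 0.5 - 0.5 / (n + 1)) < 0.03

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            permutation_p(1.0, [])
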