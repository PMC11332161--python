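"""The statistical battery against hand-worked and formula oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import newsmeta as nm

from oracles import jzs_bf10_reference, spearman_reference, welch_ttest_reference


class TestAnova2x2:
    # balanced toy: cells (A1,B1)=(1,2) (A1,B2)=(3,5) (A2,B1)=(2,4) (A2,B2)=(7,9)
    dv = [1, 2, 3, 5, 2, 4, 7, 9]
    fa = ["a1"] * 4 + ["a2"] * 4
    fb = ["b1", "b1", "b2", "b2"] * 2

    def test_matches_hand_computed_sums_of_squares(self):
        res = {r.effect: r for r in nm.anova_2x2_between(self.dv, self.fa, self.fb)}
        # hand decomposition: SS_A=15.125, SS_B=28.125, SS_AB=3.125, SS_err=6.5 (df 4)
        assert res["A"].F == pytest.approx(15.125 / 1.625, abs=1e-9)
        assert res["B"].F == pytest.approx(28.125 / 1.625, abs=1e-9)
        assert res["A x B"].F == pytest.approx(3.125 / 1.625, abs=1e-9)
        assert res["A"].MSE == pytest.approx(1.625)
        assert res["A"].df_num == 1 and res["A"].df_den == 4
        assert res["B"].partial_eta_squared == pytest.approx(28.125 / 34.625)

    def test_null_cells_give_zero_f(self):
        dv = [1, 3, 1, 3, 1, 3, 1, 3]  # identical cell means, within-cell spread
        for r in nm.anova_2x2_between(dv, self.fa, self.fb):
            assert r.F == pytest.approx(0.0, abs=1e-10)
            assert r.partial_eta_squared == pytest.approx(0.0, abs=1e-10)

    def test_balanced_decomposition_is_exhaustive(self):
        rng = np.random.default_rng(8)
        dv = rng.standard_normal(40)
        fa = np.repeat(["a1", "a2"], 20)
        fb = np.tile(np.repeat(["b1", "b2"], 10), 2)
        res = nm.anova_2x2_between(dv, fa, fb)
        ss_effects = sum(r.F * r.MSE * r.df_num for r in res)
        ss_err = res[0].MSE * res[0].df_den
        ss_total = ((dv - dv.mean()) ** 2).sum()
        assert ss_effects + ss_err == pytest.approx(ss_total, abs=1e-8)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            nm.anova_2x2_between([1, 2, 3], ["a1", "a1", "a2"], ["b1", "b2", "b1"])

    def test_two_group_reduction_agrees_with_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(12) + 0.5, rng.standard_normal(15)
        one = nm.anova_oneway(np.r_[a, b], ["x"] * 12 + ["y"] * 15)
        tt = nm.ttest(a, b, variant="pooled")
        assert one.F == pytest.approx(tt.t**2, rel=1e-9)


class TestAnovaOneway:
    def test_matches_hand_computation(self):
        dv = [1, 2, 2, 4, 5, 5, 8, 9]
        grp = ["g1", "g1", "g2", "g2", "g3", "g3", "g4", "g4"]
        res = nm.anova_oneway(dv, grp, order=["g1", "g2", "g3", "g4"])
        # SSB = 55 (df 3), SSW = 3 (df 4)
        assert res.F == pytest.approx((55 / 3) / (3 / 4), abs=1e-9)
        assert res.df_num == 3 and res.df_den == 4
        assert res.MSE == pytest.approx(0.75)
        assert res.partial_eta_squared == pytest.approx(55 / 58)

    def test_equal_means_give_zero_f(self):
        res = nm.anova_oneway([1, 3, 1, 3, 1, 3, 1, 3], list("aabbccdd"))
        assert res.F == pytest.approx(0.0, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty"):
            nm.anova_oneway([1, 2, 3], ["a", "a", "a"])


class TestMixedAnova:
    def toy(self):
        return pd.DataFrame(
            {
                "subject_id": ["s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"],
                "party": ["p", "p", "p", "p", "q", "q", "q", "q"],
                "item_type": ["x", "y"] * 4,
                "dv": [2, 4, 3, 5, 6, 6, 7, 9],
            }
        )

    def test_matches_hand_worked_decomposition(self):
        res = {r.effect: r for r in nm.mixed_anova_2x2(self.toy())}
        # between: SS=24.5 vs subjects-within-groups MS=2.5 -> F(1,2)=9.8
        # within: SS=4.5 vs error MS=0.5 -> F(1,2)=9; interaction: 0.5/0.5=1
        assert res["party"].F == pytest.approx(9.8, abs=1e-9)
        assert res["item_type"].F == pytest.approx(9.0, abs=1e-9)
        assert res["party x item_type"].F == pytest.approx(1.0, abs=1e-9)
        assert res["party"].df_num == 1 and res["party"].df_den == 2

    def test_balanced_item_types_give_zero_within_f(self):
        df = self.toy()
        df["dv"] = [2, 3, 3, 2, 6, 7, 7, 6]  # item-type means equal
        res = {r.effect: r for r in nm.mixed_anova_2x2(df)}
        assert res["item_type"].F == pytest.approx(0.0, abs=1e-10)

    def test_missing_within_level_rejected(self):
        df = self.toy().drop(index=1)
        with pytest.raises(ValueError, match="missing within-level"):
            nm.mixed_anova_2x2(df)


class TestTTest:
    a = np.array([1.1, 2.3, 2.9, 3.6, 4.1])
    b = np.array([0.4, 0.9, 1.6, 2.2, 2.5])

    def test_matches_welch_formula_oracle(self):
        res = nm.ttest(self.a, self.b)
        t, df, ci = welch_ttest_reference(self.a, self.b)
        assert res.t == pytest.approx(t, abs=1e-9)
        assert res.df == pytest.approx(df, abs=1e-6)
        assert res.ci95[0] == pytest.approx(ci[0], abs=1e-6)
        assert res.ci95[1] == pytest.approx(ci[1], abs=1e-6)
        # Cohen's d via pooled sd
        sp = np.sqrt((self.a.var(ddof=1) + self.b.var(ddof=1)) / 2)
        assert res.cohens_d == pytest.approx((self.a.mean() - self.b.mean()) / sp, abs=1e-9)

    def test_identical_groups_are_null(self):
        res = nm.ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.cohens_d == 0.0
        assert res.ci95[0] < 0 < res.ci95[1]

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            nm.ttest([2.0, 2.0], [3.0, 3.0])


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert nm.spearman(x, x**3)[0] == pytest.approx(1.0)
        assert nm.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_manual_ranking(self):
        x = np.array([1, 2, 2, 3, 4, 5, 6, 7, 8, 9.0])
        y = np.array([2, 1, 3, 3, 5, 4, 7, 6, 8, 8.0])
        rho, _ = nm.spearman(x, y)
        assert rho == pytest.approx(spearman_reference(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            nm.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestRegression:
    def test_single_standardized_predictor_equals_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(50)
        y = 0.6 * x + rng.standard_normal(50)
        out = nm.regression_std(y, pd.DataFrame({"x": x}))
        assert out.loc["x", "beta"] == pytest.approx(sps.pearsonr(x, y).statistic, abs=1e-9)

    def test_matches_normal_equations_on_toy_design(self):
        X = pd.DataFrame({"u": [1, 2, 3, 4, 5, 6.0], "v": [2, 1, 4, 3, 7, 5.0]})
        y = np.array([1.0, 2.5, 2.0, 4.0, 5.5, 5.0])
        out = nm.regression_std(y, X)
        Xz = (X - X.mean()) / X.std(ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        A = np.column_stack([np.ones(6), Xz])
        beta = np.linalg.solve(A.T @ A, A.T @ yz)
        assert out["beta"].to_numpy() == pytest.approx(beta[1:], abs=1e-9)

    def test_collinear_design_names_columns(self):
        X = pd.DataFrame({"a": [1, 2, 3, 4, 5, 6.0]})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            nm.regression_std(np.arange(6.0), X)


class TestSensitivity:
    def test_study_design_minimal_effect(self):
        f = nm.sensitivity_f(500, 4, 0.05, 0.95)
        assert round(f, 2) == 0.19

    def test_inversion_against_noncentral_f_formula(self):
        f = nm.sensitivity_f(500, 4, 0.05, 0.95)
        lam = f * f * 500
        crit = sps.f.isf(0.05, 3, 496)
        assert sps.ncf.sf(crit, 3, 496, lam) == pytest.approx(0.95, abs=1e-5)
        assert lam == pytest.approx(17.31, abs=0.01)

    def test_monotone_in_power_and_n(self):
        f1 = nm.sensitivity_f(500, 4, 0.05, 0.80)
        f2 = nm.sensitivity_f(500, 4, 0.05, 0.95)
        f3 = nm.sensitivity_f(1000, 4, 0.05, 0.95)
        assert f1 < f2 and f3 < f2

    def test_chance_power_detects_nothing(self):
        assert nm.sensitivity_f(500, 4, 0.05, 0.051) < 0.02

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nm.sensitivity_f(3, 4)
        with pytest.raises(ValueError):
            nm.sensitivity_f(500, 4, 0.5, 0.2)


class TestQuartiles:
    def test_assignment_matches_hand_ranking(self):
        dp = [3, 1, 4, 2, 8, 6, 7, 5]
        mr = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        out = nm.quartile_analysis(dp, mr)
        assert list(out["quartile"]) == [2, 1, 2, 1, 4, 3, 4, 3]

    def test_constructed_monotone_coupling_shows_in_means(self):
        rng = np.random.default_rng(4)
        dp = rng.uniform(0.5, 2.5, 80)
        mr = 0.4 + 0.2 * dp + rng.normal(0, 0.02, 80)
        out = nm.quartile_analysis(dp, mr)
        means = [out["quartile_means"][q] for q in (1, 2, 3, 4)]
        assert means == sorted(means)
        assert out["anova"].p < 0.001

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            nm.quartile_analysis([1, 2, 3], [1, 2, 3])


class TestSplithalf:
    def test_cross_half_structure(self):
        rng = np.random.default_rng(9)
        n = 40
        d_true = rng.uniform(0.8, 2.2, n)
        half = lambda: pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "d_prime": d_true + rng.normal(0, 0.15, n),
                "m_ratio": rng.normal(0.8, 0.2, n),
            }
        )
        out = nm.splithalf_check(half(), half())
        assert out["n"] == n
        assert out["d_prime_reliability_rho"] > 0.8
        assert out["a_quartiles_vs_b_mratio"].df_num == 3


class TestBayesFactor:
    def test_null_data_favor_the_null(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal(10)
        bf01 = nm.jzs_bf01_ttest(a, a)  # t = 0 at n = 10
        assert bf01 > 1

    def test_huge_null_sample_gives_strong_null_support(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(3000)
        assert nm.jzs_bf01_ttest(a, a) > 3

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(20) + 0.4
        b = rng.standard_normal(25)
        t = sps.ttest_ind(a, b, equal_var=True).statistic
        expected = 1.0 / jzs_bf10_reference(float(t), 20, 25)
        assert nm.jzs_bf01_ttest(a, b) == pytest.approx(expected, rel=1e-3)
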