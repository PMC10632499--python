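import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splitstat as ss
from splitstat.exceptions import (
    CollinearityError,
    EmptyCellError,
    InvalidFactorError,
    InvalidParameterError,
    InvalidSizeError,
    PowerNotAchievableError,
    TermLookupError,
    UndefinedCorrelationError,
)
from splitstat.linear_model import FactorialANOVA, achieved_power

from oracles import normal_equations_ols, point_biserial_toy, type3_anova_oracle


class TestPearson:
    def test_collinear_columns(self):
        x = np.arange(10.0)
        res = ss.pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.variance_explained == pytest.approx(1.0)

    def test_variance_explained_is_r_squared(self, rng):
        x = rng.standard_normal(200)
        y = 0.3 * x + rng.standard_normal(200)
        res = ss.pearson_r(x, y)
        assert res.variance_explained == pytest.approx(res.r**2)

    def test_point_biserial_equals_hand_formula(self):
        groups = np.array([0, 0, 0, 1, 1, 1])
        y = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 8.0])
        res = ss.pearson_r(groups, y)
        assert res.r == pytest.approx(point_biserial_toy(groups, y), abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            ss.pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_tiny_sample_rejected(self):
        with pytest.raises(InvalidSizeError):
            ss.pearson_r([1.0, 2.0], [3.0, 4.0])


class TestModeratedOLS:
    def test_exact_line(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [2.0, 5.0, 8.0]})
        fit = ss.ModeratedOLS(df, "y", ["x"]).fit()
        assert fit.params["const"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["x"] == pytest.approx(3.0, abs=1e-10)
        assert fit.rsquared == pytest.approx(1.0)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-20)

    def test_interaction_fixture_matches_normal_equations(self):
        df = pd.DataFrame(
            {
                "x": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
                "z": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                "y": [1.0, 2.5, 3.1, 2.2, 4.8, 7.9],
            }
        )
        fit = ss.ModeratedOLS(df, "y", ["x", "z", "x:z"]).fit()
        X = np.column_stack(
            [np.ones(6), df.x, df.z, df.x * df.z]
        )
        beta, r2, s2 = normal_equations_ols(X, df.y.to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-10)
        assert fit.rsquared == pytest.approx(r2, abs=1e-10)
        assert fit.resid_var == pytest.approx(s2, abs=1e-10)

    def test_study2_interaction_recovery(self):
        df = ss.generate_study2(50_000, seed=21)
        fit = ss.ModeratedOLS(
            df, "fv_intake", ["cognitive_restraint", "bmi", "cognitive_restraint:bmi"],
            center=True,
        ).fit()
        b = fit.params["cognitive_restraint:bmi"]
        assert abs(b - (-2.84)) < 4 * fit.bse["cognitive_restraint:bmi"] + 0.05 * 2.84

    def test_rank_deficiency_names_offending_term(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.standard_normal(30)})
        df["z"] = 2 * df["x"]
        df["y"] = rng.standard_normal(30)
        with pytest.raises(CollinearityError) as exc:
            ss.ModeratedOLS(df, "y", ["x", "z"]).fit()
        assert "z" in exc.value.terms

    def test_unknown_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(TermLookupError):
            ss.ModeratedOLS(df, "y", ["x", "w"])

    def test_centering_invariance_of_highest_order_term(self, study2_table):
        terms = ["cognitive_restraint", "bmi", "cognitive_restraint:bmi"]
        raw = ss.ModeratedOLS(study2_table, "fv_intake", terms).fit()
        cen = ss.ModeratedOLS(study2_table, "fv_intake", terms, center=True).fit()
        key = "cognitive_restraint:bmi"
        assert cen.params[key] == pytest.approx(raw.params[key], abs=1e-10)
        assert cen.bse[key] == pytest.approx(raw.bse[key], abs=1e-10)
        assert cen.rsquared == pytest.approx(raw.rsquared, abs=1e-10)
        assert cen.tvalues[key] == pytest.approx(raw.tvalues[key], abs=1e-8)

    def test_centering_recorded(self, study2_table):
        fit = ss.ModeratedOLS(
            study2_table, "fv_intake", ["cognitive_restraint", "bmi"], center=["bmi"]
        ).fit()
        assert fit.centering == {"bmi": pytest.approx(study2_table["bmi"].mean())}


class TestPartialStatistics:
    def test_single_predictor_semipartial_is_r_squared(self, rng):
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        df = pd.DataFrame({"x": x, "y": y})
        fit = ss.ModeratedOLS(df, "y", ["x"]).fit()
        r2 = ss.pearson_r(x, y).variance_explained
        assert fit.squared_semipartial("x") == pytest.approx(r2, abs=1e-12)

    def test_partial_matches_t_identity(self, study2_fit):
        for term in study2_fit.model.terms:
            t = study2_fit.tvalues[term]
            expected = t * t / (t * t + study2_fit.df_resid)
            assert study2_fit.squared_partial(term) == pytest.approx(expected)

    def test_semipartial_matches_two_model_refit(self):
        df = pd.DataFrame(
            {
                "x": [0.0, 1.0, 2.0, 0.0, 1.0, 2.0],
                "z": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
                "y": [1.0, 2.5, 3.1, 2.2, 4.8, 7.9],
            }
        )
        fit = ss.ModeratedOLS(df, "y", ["x", "z"]).fit()
        X_full = np.column_stack([np.ones(6), df.x, df.z])
        X_red = np.column_stack([np.ones(6), df.z])
        _, r2_full, _ = normal_equations_ols(X_full, df.y.to_numpy())
        _, r2_red, _ = normal_equations_ols(X_red, df.y.to_numpy())
        assert fit.squared_semipartial("x") == pytest.approx(r2_full - r2_red, abs=1e-12)

    def test_unknown_term_rejected(self, study2_fit):
        with pytest.raises(TermLookupError):
            study2_fit.squared_partial("nope")


def _toy_2x2() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "y": [1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0],
            "a": ["a1"] * 4 + ["a2"] * 4,
            "b": ["b1", "b1", "b2", "b2"] * 2,
        }
    )


class TestFactorialANOVA:
    def test_balanced_2x2_hand_values(self):
        res = FactorialANOVA(_toy_2x2(), "y", "a", "b").fit()
        tab = res.table
        assert tab.loc["a", "sum_sq"] == pytest.approx(32.0, abs=1e-10)
        assert tab.loc["b", "sum_sq"] == pytest.approx(2.0, abs=1e-10)
        assert tab.loc["a:b", "sum_sq"] == pytest.approx(0.0, abs=1e-10)
        assert tab.loc["Residual", "sum_sq"] == pytest.approx(8.0, abs=1e-10)
        assert tab.loc["a", "F"] == pytest.approx(16.0, abs=1e-10)
        assert res.partial_eta_sq("a") == pytest.approx(0.8, abs=1e-12)

    def test_additive_cells_have_zero_interaction(self):
        df = _toy_2x2()  # cell means 2,3,6,7: perfectly additive
        res = FactorialANOVA(df, "y", "a", "b").fit()
        assert res.table.loc["a:b", "sum_sq"] == pytest.approx(0.0, abs=1e-10)

    def test_unbalanced_type3_matches_effect_coded_increments(self, rng):
        n = 120
        a = rng.choice(["low", "high"], size=n, p=[0.7, 0.3])
        b = rng.choice(["g1", "g2", "g3"], size=n)
        y = rng.standard_normal(n) + (a == "high") * 0.5 + (b == "g3") * 1.0
        df = pd.DataFrame({"y": y, "a": a, "b": b})
        res = FactorialANOVA(df, "y", "a", "b").fit()
        oracle = type3_anova_oracle(y, a, b)
        for mine, theirs in (("a", "A"), ("b", "B"), ("a:b", "A:B")):
            ss_eff, df_eff, F = oracle[theirs]
            assert res.table.loc[mine, "sum_sq"] == pytest.approx(ss_eff, abs=1e-10)
            assert res.table.loc[mine, "df"] == df_eff
            assert res.table.loc[mine, "F"] == pytest.approx(F, abs=1e-10)

    def test_balanced_decomposition_sums_to_total(self):
        df = _toy_2x2()
        res = FactorialANOVA(df, "y", "a", "b").fit()
        total = ((df.y - df.y.mean()) ** 2).sum()
        parts = res.table["sum_sq"].sum()
        assert parts == pytest.approx(total, rel=1e-8)

    def test_2x2_f_equals_squared_effect_coded_t(self, study2_table):
        df = study2_table.copy()
        for col in ("cognitive_restraint", "bmi"):
            scheme = ss.median_split(df[col])
            df[f"{col}_g"] = np.asarray(ss.apply_cut(df[col], scheme).labels)
        res = FactorialANOVA(df, "fv_intake", "cognitive_restraint_g", "bmi_g").fit()
        a = np.where(df["cognitive_restraint_g"] == "high", 1.0, -1.0)
        b = np.where(df["bmi_g"] == "high", 1.0, -1.0)
        X = np.column_stack([np.ones(len(df)), a, b, a * b])
        y = df["fv_intake"].to_numpy()
        beta, _, s2 = normal_equations_ols(X, y)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
        t2 = (beta / se) ** 2
        assert res.table.loc["cognitive_restraint_g", "F"] == pytest.approx(t2[1], abs=1e-8)
        assert res.table.loc["bmi_g", "F"] == pytest.approx(t2[2], abs=1e-8)
        assert res.table.loc["cognitive_restraint_g:bmi_g", "F"] == pytest.approx(t2[3], abs=1e-8)

    def test_empty_cell_rejected(self):
        df = _toy_2x2().iloc[[0, 1, 4, 5, 6, 7]]  # no (a1, b2) cell
        with pytest.raises(EmptyCellError):
            FactorialANOVA(df, "y", "a", "b")

    def test_single_level_factor_rejected(self):
        df = _toy_2x2()
        df["a"] = "only"
        with pytest.raises(InvalidFactorError):
            FactorialANOVA(df, "y", "a", "b")


class TestPosthoc:
    def test_two_level_factor_single_unadjusted_contrast(self):
        res = FactorialANOVA(_toy_2x2(), "y", "a", "b").fit()
        ph = res.bonferroni_posthoc("a")
        assert len(ph) == 1
        assert ph.p_bonferroni[0] == pytest.approx(ph.p_raw[0])

    def test_four_level_factor_six_capped_contrasts(self, rng):
        n = 80
        b = rng.choice(list("wxyz"), size=n)
        df = pd.DataFrame(
            {"y": rng.standard_normal(n), "a": rng.choice(["l", "h"], size=n), "b": b}
        )
        res = FactorialANOVA(df, "y", "a", "b").fit()
        ph = res.bonferroni_posthoc("b")
        assert len(ph) == 6
        assert (ph.p_bonferroni <= 1.0).all()
        np.testing.assert_allclose(
            ph.p_bonferroni, np.minimum(1.0, ph.p_raw * 6), atol=1e-12
        )

    def test_outlier_level_drives_significance(self, rng):
        n = 240
        b = rng.choice(["g1", "g2", "g3"], size=n)
        a = rng.choice(["l", "h"], size=n)
        y = rng.standard_normal(n) + np.where(b == "g3", 8.0, 0.0)
        res = FactorialANOVA(pd.DataFrame({"y": y, "a": a, "b": b}), "y", "a", "b").fit()
        ph = res.bonferroni_posthoc("b")
        for row in ph.itertuples():
            involves_g3 = "g3" in (row.level_1, row.level_2)
            assert (row.p_bonferroni < 0.05) == involves_g3


class TestEffectSizes:
    def test_cohens_d_examples(self):
        assert ss.cohens_d(2.0, 6.0, 2.0) == pytest.approx(2.0)
        assert ss.cohens_d(3.0, 3.0, 1.0) == 0.0
        with pytest.raises(InvalidParameterError):
            ss.cohens_d(1.0, 2.0, 0.0)

    def test_cohens_d_pooled_hand_computation(self):
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([4.0, 6.0, 8.0])
        sp = np.sqrt(((len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1))
                     / (len(g1) + len(g2) - 2))
        assert ss.cohens_d(g1.mean(), g2.mean(), sp) == pytest.approx(
            (g2.mean() - g1.mean()) / sp
        )

    def test_f_squared_values(self):
        assert ss.f_squared(0.015, 0.125) == pytest.approx(0.015 / 0.875)
        assert ss.f_squared(0.025, 0.125) == pytest.approx(0.025 / 0.875)
        assert ss.f_squared(0.0, 0.5) == 0.0
        with pytest.raises(InvalidParameterError):
            ss.f_squared(0.5, 1.0)


class TestPower:
    def test_required_n_is_minimal(self):
        res = ss.required_n(0.015 / 0.875, 1, 3)
        n = res.required_n
        assert achieved_power(res.f2, 1, 3, n) >= 0.80
        assert achieved_power(res.f2, 1, 3, n - 1) < 0.80

    def test_power_monotone_in_n_and_effect(self):
        f2 = 0.02
        powers = [achieved_power(f2, 1, 3, n) for n in (100, 200, 400, 800)]
        assert all(p2 > p1 for p1, p2 in zip(powers, powers[1:]))
        at_n = [achieved_power(f, 1, 3, 300) for f in (0.01, 0.02, 0.05, 0.1)]
        assert all(p2 > p1 for p1, p2 in zip(at_n, at_n[1:]))

    def test_zero_effect_rejected(self):
        with pytest.raises(PowerNotAchievableError):
            ss.required_n(0.0, 1, 3)

    def test_large_effect_small_n_monte_carlo(self, rng):
        """Noncentral-F power cross-checked by simulating the F statistic."""
        f2, u, p_full = 1.0, 1, 1
        res = ss.required_n(f2, u, p_full, alpha=0.05, power_target=0.80)
        n = res.required_n
        v = n - p_full - 1
        lam = f2 * (u + v + 1)
        reps = 20_000
        fstat = (rng.noncentral_chisquare(u, lam, reps) / u) / (
            rng.chisquare(v, reps) / v
        )
        crit = stats.f.isf(0.05, u, v)
        rate = (fstat > crit).mean()
        mc_se = np.sqrt(rate * (1 - rate) / reps)
        assert abs(rate - res.achieved_power) < 2 * mc_se + 1e-3
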