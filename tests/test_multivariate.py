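"""Regression/MANOVA machinery: oracles, reductions, subgroups, design."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA

from collatscore.design import DESIGN_COLUMNS
from collatscore.multivariate import (
    ModelError,
    SubgroupSpec,
    build_design,
    fit_manova,
    fit_ols,
    subgroup_filter,
)

# ---------------------------------------------------------------------------
# brute-force normal-equations oracle


def oracle_ols(y, X):
    """(coef, se, r2, adj_r2) via explicit normal equations."""
    y = np.asarray(y, float)
    D = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    XtX_inv = np.linalg.inv(D.T @ D)
    beta = XtX_inv @ D.T @ y
    resid = y - D @ beta
    n, k = D.shape
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    ss_res = resid @ resid
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot
    adj = 1 - (1 - r2) * (n - 1) / (n - k)
    return beta, se, r2, adj


class TestFitOls:
    def test_noise_free_linear_fit_is_exact(self):
        x = np.arange(10.0)
        fit = fit_ols(2 * x + 5, pd.DataFrame({"x": x}))
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coef["x"] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(5.0)

    def test_eight_row_fixture_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(8, 2)), columns=["a", "b"])
        y = 1.0 + 0.5 * X["a"] - 2.0 * X["b"] + rng.normal(size=8)
        fit = fit_ols(y, X)
        beta, se, r2, adj = oracle_ols(y, X)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.coef["a"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.coef["b"] == pytest.approx(beta[2], abs=1e-10)
        assert fit.se["a"] == pytest.approx(se[1], abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(adj, abs=1e-12)

    def test_oracle_agreement_on_random_problems(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 40))
            p = int(rng.integers(1, 5))
            X = pd.DataFrame(
                rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)]
            )
            y = rng.normal(size=n) + X.to_numpy() @ rng.normal(size=p)
            fit = fit_ols(y, X)
            beta, se, r2, adj = oracle_ols(y, X)
            got = np.array([fit.coef[c] for c in X.columns])
            assert np.allclose(got, beta[1:], rtol=1e-8)
            assert np.allclose([fit.se[c] for c in X.columns], se[1:], rtol=1e-8)
            assert fit.adj_r2 == pytest.approx(adj, rel=1e-8, abs=1e-10)
            assert fit.df_resid == n - p - 1

    def test_standardized_beta_equals_zscored_refit(self, rng):
        n = 60
        X = pd.DataFrame(
            {
                "cont": rng.normal(size=n),
                "bin": (rng.random(n) < 0.3).astype(float),
            }
        )
        y = X["cont"] - 0.8 * X["bin"] + rng.normal(size=n)
        fit = fit_ols(y, X)
        Xs = (X - X.mean()) / X.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        ref = fit_ols(ys, Xs)
        for c in X.columns:
            assert fit.beta_std[c] == pytest.approx(ref.coef[c], abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ModelError, match="rank deficient.*'[ab]'"):
            fit_ols(rng.normal(size=30), X)

    def test_insufficient_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ModelError, match="insufficient"):
            fit_ols(rng.normal(size=4), X)

    def test_listwise_deletion_counts(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        X.loc[3, "a"] = np.nan
        y = pd.Series(rng.normal(size=30))
        fit = fit_ols(y, X)
        assert fit.n_used == 29

    def test_noise_column_never_decreases_r2(self, rng):
        for _ in range(20):
            n = 40
            X = pd.DataFrame({"a": rng.normal(size=n)})
            y = X["a"] + rng.normal(size=n)
            base = fit_ols(y, X)
            wide = fit_ols(y, X.assign(junk=rng.normal(size=n)))
            assert wide.r2 >= base.r2 - 1e-12


class TestManova:
    def test_matches_statsmodels_pillai(self, rng):
        n = 70
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        Y = pd.DataFrame(rng.normal(size=(n, 3)), columns=["y1", "y2", "y3"])
        Y["y1"] += 0.5 * X["a"]
        fit = fit_manova(Y, X)
        mod = MANOVA(Y.to_numpy(), sm.add_constant(X).to_numpy())
        for i, name in enumerate(["a", "b", "c"], start=1):
            L = np.zeros((1, 4))
            L[0, i] = 1
            ref = mod.mv_test(hypotheses=[(name, L, None)]).results[name]["stat"]
            row = ref.loc["Pillai's trace"]
            assert fit.terms[name]["pillai"] == pytest.approx(row["Value"], abs=1e-10)
            assert fit.terms[name]["f_value"] == pytest.approx(row["F Value"], abs=1e-8)
            assert fit.terms[name]["df1"] == row["Num DF"]
            assert fit.terms[name]["df2"] == row["Den DF"]
            assert fit.terms[name]["p"] == pytest.approx(row["Pr > F"], abs=1e-10)

    def test_single_outcome_reduces_to_ols_overall_f(self, rng):
        n = 50
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = rng.normal(size=n) + X["a"]
        fit = fit_manova(pd.DataFrame({"y": y}), X)
        ols = fit_ols(y, X)
        assert fit.terms["omnibus"]["f_value"] == pytest.approx(ols.f_value, abs=1e-8)
        assert fit.terms["omnibus"]["p"] == pytest.approx(ols.f_pvalue, abs=1e-10)
        assert (fit.terms["omnibus"]["df1"], fit.terms["omnibus"]["df2"]) == (
            ols.df_model,
            ols.df_resid,
        )

    def test_duplicated_outcome_column_rejected(self, rng):
        n = 40
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = rng.normal(size=n)
        Y = pd.DataFrame({"y1": y, "y2": y})
        with pytest.raises(ModelError, match="singular residual covariance"):
            fit_manova(Y, X)

    def test_planted_effect_detected(self, analysis_cohort):
        df = analysis_cohort.table
        Y = pd.concat(
            [
                np.log1p(df["fiv_ml"]).rename("log1p_fiv"),
                df["nihss_discharge"],
                df["mrs_discharge"],
            ],
            axis=1,
        )
        X = build_design(analysis_cohort)
        joined = pd.concat([Y, X], axis=1).dropna()
        fit = fit_manova(joined.iloc[:, :3], joined.iloc[:, 3:])
        assert fit.terms["whole_brain_score"]["p"] < 0.05


class TestSubgroups:
    def test_all_spec_is_identity(self, analysis_cohort):
        sub = subgroup_filter(analysis_cohort, SubgroupSpec("all"))
        assert len(sub) == len(analysis_cohort)

    def test_territory_filter(self, analysis_cohort):
        sub = subgroup_filter(analysis_cohort, SubgroupSpec("mca", territory="MCA"))
        assert (sub.table["territory"] == "MCA").all()
        assert len(sub) == (analysis_cohort.table["territory"] == "MCA").sum()

    def test_fiv_band(self, analysis_cohort):
        spec = SubgroupSpec("medium", fiv_min=15.0, fiv_max=100.0)
        sub = subgroup_filter(analysis_cohort, spec)
        assert sub.table["fiv_ml"].between(15, 100).all()

    def test_malignant_profile_is_a_union(self, analysis_cohort):
        spec = SubgroupSpec("malignant", fiv_min=100.0, nihss_gt=17.0, combine="any")
        sub = subgroup_filter(analysis_cohort, spec)
        df = sub.table
        assert (((df["fiv_ml"] >= 100) | (df["nihss_discharge"] > 17))).all()
        n_union = (
            (analysis_cohort.table["fiv_ml"] >= 100)
            | (analysis_cohort.table["nihss_discharge"] > 17)
        ).sum()
        assert len(sub) == n_union

    def test_nothing_matches_gives_empty_cohort(self, analysis_cohort):
        sub = subgroup_filter(analysis_cohort, SubgroupSpec("none", fiv_min=1e12))
        assert len(sub) == 0

    def test_min_n_guard_validated(self):
        with pytest.raises(ValueError, match="min_n"):
            SubgroupSpec("tiny", min_n=5)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="fiv_min"):
            SubgroupSpec("bad", fiv_min=100.0, fiv_max=15.0)


class TestBuildDesign:
    def test_complete_cohort_design_shape(self, analysis_cohort):
        X = build_design(analysis_cohort)
        assert list(X.columns) == list(DESIGN_COLUMNS)
        # rows with a missing treatment record drop out listwise
        assert len(X) == int(analysis_cohort.table["treatment"].notna().sum())

    def test_untreated_patients_have_zero_dummies(self, analysis_cohort):
        X = build_design(analysis_cohort)
        untreated = analysis_cohort.table.loc[X.index, "treatment"] == "none"
        assert (X.loc[untreated, ["tx_iv", "tx_ia", "tx_thrombectomy"]] == 0).all().all()

    def test_missing_age_row_dropped(self, analysis_cohort):
        df = analysis_cohort.table.copy()
        complete = df["treatment"].notna()
        idx = df.index[complete][0]
        df.loc[idx, "age"] = np.nan
        X = build_design(df)
        assert len(X) == complete.sum() - 1
        assert idx not in X.index

    def test_missing_column_reported(self, analysis_cohort):
        df = analysis_cohort.table.drop(columns=["statin"])
        with pytest.raises(KeyError, match="statin"):
            build_design(df)
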