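"""Mixed-model fitting, AICc selection, and Pearson tests.

The mixed-model path is cross-validated against values computed
independently with R nlme's lme() on a frozen simulated dataset.
"""

import numpy as np
import pandas as pd
import pytest

import baleen_cycles as bc
from baleen_cycles.datasets import cycle_summary
from baleen_cycles.trend_models import (
    ConvergenceError,
    aicc,
    denominator_df,
    fit_lmm,
    pearson_corr_test,
    select_model,
)
from conftest import study_shape_lmm_data


def nlme_oracle_data() -> pd.DataFrame:
    """Frozen dataset whose ML/REML fits were computed with R nlme."""
    rng = np.random.default_rng(3)
    rows = []
    for w in range(9):
        b0 = rng.normal(0, 2)
        b1 = rng.normal(0, 0.1)
        for age in np.arange(10 + w, 25 + w):
            rows.append(
                (f"w{w}", float(age), 10 + b0 + (-0.1 + b1) * age + rng.normal(0, 1))
            )
    return pd.DataFrame(rows, columns=["whale_id", "age", "response"])


class TestAicc:
    def test_closed_form(self):
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_penalty_positive(self):
        assert aicc(-259.5, 6, 126) > 2 * 259.5

    def test_converges_to_aic_for_large_n(self):
        k, ll = 5, -100.0
        assert aicc(ll, k, 10**6) - (-2 * ll + 2 * k) < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestDenominatorDf:
    def test_study_shape(self):
        assert denominator_df(126, 9, 1) == 116

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            denominator_df(9, 9, 1)


class TestFitLmm:
    def test_matches_r_nlme_ml(self):
        fit = fit_lmm(nlme_oracle_data(), "random_intercept_slope", "ML")
        assert fit.loglik == pytest.approx(-224.4969, abs=1e-3)
        est = fit.fixed_effects["estimate"]
        assert est["intercept"] == pytest.approx(8.711288, abs=1e-3)
        assert est["age"] == pytest.approx(-0.0979923, abs=1e-5)

    def test_matches_r_nlme_reml(self):
        fit = fit_lmm(nlme_oracle_data(), "random_intercept_slope", "REML")
        assert fit.loglik == pytest.approx(-226.1656, abs=1e-3)
        est = fit.fixed_effects["estimate"]
        assert est["intercept"] == pytest.approx(8.703806, abs=1e-3)
        assert est["age"] == pytest.approx(-0.09772611, abs=1e-5)

    def test_zero_between_whale_variance_matches_ols(self):
        """With no whale-level heterogeneity the mixed fit collapses to
        ordinary least squares."""
        rng = np.random.default_rng(42)
        df = study_shape_lmm_data(
            rng, slope_sd=0.0, fixed_slope=-0.1, intercept_sd=0.0, resid_sd=1.0
        )
        fit = fit_lmm(df, "random_intercept", "ML")
        X = np.column_stack([np.ones(len(df)), df["age"]])
        ols = np.linalg.lstsq(X, df["response"], rcond=None)[0]
        np.testing.assert_allclose(fit.fixed_effects["estimate"], ols, atol=1e-4)
        assert fit.boundary_variance

    def test_denominator_df_at_study_shape(self):
        rng = np.random.default_rng(1)
        df = study_shape_lmm_data(rng, slope_sd=0.2, fixed_slope=-0.163)
        assert len(df) == 126
        fit = fit_lmm(df, "random_intercept_slope", "ML")
        assert int(fit.fixed_effects.loc["age", "df"]) == 116

    def test_fixed_slope_recovery_within_2se(self, lmm_slope_recovery):
        """At the study's shape (9 whales, 126 peaks, slope SD 0.2) the
        REML fixed slope lies within 2 SE of truth in >= 90% of 100
        replicates."""
        assert lmm_slope_recovery["hits"] >= 90

    def test_nesting_monotonicity_of_ml_loglik(self):
        df = nlme_oracle_data()
        ll = {
            v: fit_lmm(df, v, "ML").loglik
            for v in ("null", "random_intercept", "random_intercept_slope")
        }
        assert ll["random_intercept"] >= ll["null"] - 1e-6
        assert ll["random_intercept_slope"] >= ll["random_intercept"] - 1e-6

    def test_per_whale_coefficients_shrink_toward_fixed(self):
        fit = fit_lmm(nlme_oracle_data(), "random_intercept_slope", "REML")
        assert set(fit.per_whale.index) == {f"w{i}" for i in range(9)}
        fixed_slope = fit.fixed_effects.loc["age", "estimate"]
        assert fit.per_whale["slope"].mean() == pytest.approx(fixed_slope, abs=0.05)

    def test_single_group_rejected(self):
        df = pd.DataFrame(
            {"whale_id": ["a"] * 10, "age": np.arange(10.0), "response": np.arange(10.0)}
        )
        with pytest.raises(ValueError):
            fit_lmm(df, "random_intercept", "ML")


class TestSelectModel:
    def test_strong_heterogeneity_selects_random_slope(self, selection_rates):
        assert selection_rates["heterogeneity"] >= 90

    def test_null_data_selects_simpler_variant(self, selection_rates):
        assert selection_rates["null"] >= 80

    def test_winner_refit_by_reml_and_ordering_consistent(self):
        rng = np.random.default_rng(5)
        df = study_shape_lmm_data(rng, slope_sd=0.3, fixed_slope=-0.163, resid_sd=1.0)
        sel = select_model(df)
        assert sel.best.estimation == "REML"
        # AICc ordering equals recomputation from the stored pieces
        for _, row in sel.comparison.iterrows():
            if row["converged"]:
                assert row["aicc"] == pytest.approx(
                    aicc(row["loglik"], int(row["k"]), 126)
                )
        best_by_table = sel.comparison.loc[sel.comparison["aicc"].idxmin(), "variant"]
        assert sel.best_variant == best_by_table
        assert 0.0 < sel.residual_normality_W <= 1.0


class TestPearson:
    def pearson_oracle(self, x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        xc, yc = x - x.mean(), y - y.mean()
        return np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_covariance_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 25))
        res = pearson_corr_test(x, y)
        assert res.r == pytest.approx(self.pearson_oracle(x, y), abs=1e-12)
        assert res.r_squared == pytest.approx(res.r**2, abs=1e-15)

    def test_reference_baseline_correlation(self):
        """Terminal age vs baseline T across the nine whales: r^2 = 0.8680,
        p = 0.0003."""
        table = cycle_summary()
        res = pearson_corr_test(table["est_age_yr"], table["baseline"])
        assert res.r_squared == pytest.approx(0.8680, abs=5e-5)
        assert res.p_two_tailed == pytest.approx(0.0003, abs=5e-5)

    def test_reference_median_correlation(self):
        table = cycle_summary()
        res = pearson_corr_test(table["est_age_yr"], table["median_t"])
        assert res.r_squared == pytest.approx(0.5274, abs=5e-5)
        assert res.p_two_tailed == pytest.approx(0.0267, abs=5e-5)

    def test_exact_linear_relationship(self):
        x = np.arange(10.0)
        res = pearson_corr_test(x, 3 * x + 2)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_two_tailed < 1e-10
        assert res.significant

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr_test(np.ones(9), np.arange(9.0))
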