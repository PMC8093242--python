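import numpy as np
import pandas as pd
import pytest

from cvsem.sem import (
    LatentRegressionModel,
    MonomorphicVariantError,
    OneFactorModel,
    chi2_pvalue,
    fit_one_factor,
    fit_variant_model,
    rmsea_with_ci,
)
from .conftest import STUDY_LOADINGS, make_category_data


class TestChi2Pvalue:
    def test_reference_statistic(self):
        # chi2 = 22.5 on 9 df -> p = 7.4e-3 at two significant figures
        assert chi2_pvalue(22.5, 9) == pytest.approx(7.4e-3, rel=0.05)

    def test_zero_statistic(self):
        for df in (1, 5, 20):
            assert chi2_pvalue(0.0, df) == 1.0

    def test_95th_percentile_of_chi2_1(self):
        assert chi2_pvalue(3.841, 1) == pytest.approx(0.050, abs=5e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-1.0, 3)
        with pytest.raises(ValueError):
            chi2_pvalue(1.0, 0)


class TestRmsea:
    def test_reference_statistic(self):
        est, lo, hi = rmsea_with_ci(22.5, 9, 1966)
        assert est == pytest.approx(0.028, abs=5e-4)
        assert 0.0 <= lo <= est <= hi

    def test_truncated_at_zero(self):
        est, lo, _ = rmsea_with_ci(5.0, 9, 500)
        assert est == 0.0 and lo == 0.0

    def test_closed_form_double_df(self):
        est, _, _ = rmsea_with_ci(18.0, 9, 1000)
        assert est == pytest.approx(np.sqrt(9 / (9 * 999)), abs=1e-12)

    def test_ci_widens_with_lower_confidence_level(self):
        _, lo90, hi90 = rmsea_with_ci(22.5, 9, 1966, confidence=0.90)
        _, lo50, hi50 = rmsea_with_ci(22.5, 9, 1966, confidence=0.50)
        assert lo50 >= lo90 and hi50 <= hi90


class TestOneFactorModel:
    def test_exact_implied_covariance_recovered(self):
        gamma = np.array([0.8, 0.6, 0.7, 0.75])
        delta = 1.0 - gamma**2
        S = np.outer(gamma, gamma) + np.diag(delta)
        res = OneFactorModel.from_covariance(S, n_obs=2000).fit()
        np.testing.assert_allclose(res.loadings, gamma, atol=1e-6)
        np.testing.assert_allclose(res.residual_variances, delta, atol=1e-6)
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)
        assert res.df == 2

    def test_independent_indicators_imply_diagonal_covariance(self, rng):
        # under the null the factor is unidentified, so individual loadings
        # can drift; the implied covariance must still be near-diagonal and
        # the fit statistic consistent with its reference distribution
        data = pd.DataFrame(rng.standard_normal((3000, 4)))
        res = OneFactorModel(data).fit()
        implied = res.implied_cov
        off = implied[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05
        from scipy import stats

        assert res.chi_square < stats.chi2.ppf(0.999, res.df)

    def test_sign_convention_first_loading_nonnegative(self, rng):
        data = make_category_data(rng, 500, loadings=STUDY_LOADINGS)
        data.iloc[:, 0] *= -1  # flip an indicator; gamma_1 stays >= 0
        res = OneFactorModel(data).fit()
        assert res.loadings[0] >= 0

    def test_scale_equivariance(self, rng):
        data = make_category_data(rng, 800)
        res1 = OneFactorModel(data).fit()
        scaled = data.copy()
        scaled.iloc[:, 2] *= 3.0
        res2 = OneFactorModel(scaled).fit()
        assert res2.loadings[2] == pytest.approx(3.0 * res1.loadings[2], rel=1e-4)
        assert res2.residual_variances[2] == pytest.approx(
            9.0 * res1.residual_variances[2], rel=1e-4
        )
        assert res2.chi_square == pytest.approx(res1.chi_square, rel=1e-5)

    def test_heywood_case_flagged_and_bounded(self, rng):
        gamma = np.array([0.995, 0.4, 0.4, 0.4])
        S = np.outer(gamma, gamma) + np.diag(
            np.array([1e-4, 0.8, 0.8, 0.8])
        )
        res = OneFactorModel.from_covariance(S, 200).fit()
        assert res.residual_variances.min() >= 1e-6 * (1 - 1e-9)

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError):
            OneFactorModel(make_category_data(rng, 30))

    def test_summary_renders(self, rng):
        res = OneFactorModel(make_category_data(rng, 300)).fit()
        text = res.summary()
        assert "chi-square" in text and "RMSEA" in text


class TestLatentRegression:
    def test_null_dosage_effect_near_zero(self, rng):
        data = make_category_data(rng, 1500)
        dosage = rng.binomial(2, 0.3, 1500).astype(float)
        res = fit_variant_model(data, dosage)
        beta, se, z, p = res.effect("dosage")
        assert abs(z) < 4.0
        assert res.converged

    def test_effect_recovery_single_fit(self, rng):
        n = 4000
        g = rng.binomial(2, 0.3, n).astype(float)
        z = (g - g.mean()) / g.std()
        latent = 0.3 * z + rng.standard_normal(n)
        data = make_category_data(rng, n, latent=latent)
        res = fit_variant_model(data, z)
        beta, se, *_ = res.effect("dosage")
        assert beta == pytest.approx(0.3, abs=3 * se)

    def test_covariate_effects_estimated(self, rng):
        n = 3000
        age = rng.uniform(-1, 1, n)
        latent = 0.4 * age + rng.standard_normal(n)
        data = make_category_data(rng, n, latent=latent)
        g = rng.binomial(2, 0.4, n).astype(float)
        res = fit_variant_model(
            data, g, covariates=pd.DataFrame({"age": age}, index=data.index)
        )
        b_age, se_age, *_ = res.effect("age")
        assert b_age == pytest.approx(0.4, abs=3 * se_age)

    def test_monomorphic_dosage_rejected(self, rng):
        data = make_category_data(rng, 200)
        with pytest.raises(MonomorphicVariantError):
            fit_variant_model(data, np.zeros(200))

    def test_wald_consistency_z_and_p(self, rng):
        data = make_category_data(rng, 800)
        res = fit_variant_model(data, rng.binomial(2, 0.3, 800).astype(float))
        from scipy import stats

        beta, se, z, p = res.effect("dosage")
        assert p == pytest.approx(2 * stats.norm.sf(abs(beta / se)), rel=1e-10)

    def test_degenerate_limit_matches_ols_on_common_component(self, rng):
        # residuals -> 0: indicators collapse onto gamma * F and the latent
        # effect equals the OLS slope of F on the dosage
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        zg = (g - g.mean()) / g.std()
        latent = 0.25 * zg + rng.standard_normal(n)
        gamma = STUDY_LOADINGS
        y = latent[:, None] * gamma + 1e-4 * rng.standard_normal((n, 4))
        data = pd.DataFrame(y, columns=list("abcd"))
        res = LatentRegressionModel(
            data, pd.DataFrame({"dosage": zg})
        ).fit()
        ols_slope = np.polyfit(zg, latent, 1)[0]
        assert res.exog_effects[0] == pytest.approx(ols_slope, abs=0.01)

    def test_chi_square_df_reduces_to_covariance_model(self, rng):
        data = make_category_data(rng, 400)
        g = rng.binomial(2, 0.3, 400).astype(float)
        res = fit_variant_model(data, g)
        # p=4, k=1: df = pk + p(p+1)/2 - (2p + k) = 4 + 10 - 9 = 5
        assert res.df == 5
        assert res.chi_square >= 0

    def test_fit_one_factor_dispatch(self, rng):
        data = make_category_data(rng, 300)
        res_cov = fit_one_factor(data)
        assert hasattr(res_cov, "chi_square") and res_cov.df == 2
        cov = pd.DataFrame({"age": rng.uniform(-1, 1, 300)}, index=data.index)
        res_reg = fit_one_factor(data, cov)
        assert "age" in res_reg.model.exog_names
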