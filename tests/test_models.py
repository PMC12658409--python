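import numpy as np
import pytest
from scipy.special import expit, logit

import gesturebias as gb
from gesturebias.models import (
    CodedFactor,
    MAJORITY_NATURAL_CODES,
    RandomInterceptLogit,
    SeparationError,
    _glmm_design,
    fit_logistic,
    fit_logistic_intercept,
    fit_logit_glmm,
    fit_ols_rating,
    likelihood_ratio_test,
)


class TestLogisticIntercept:
    def test_chance_level(self):
        fit = fit_logistic_intercept(80, 160)
        assert fit["intercept"]["coef"] == 0.0
        assert fit["intercept"]["z"] == 0.0

    def test_closed_form_at_reference_scale(self):
        fit = fit_logistic_intercept(102, 160)["intercept"]
        assert fit["coef"] == pytest.approx(0.565, abs=5e-4)
        assert fit["se"] == pytest.approx(0.164, abs=5e-4)
        assert fit["z"] == pytest.approx(3.43, abs=5e-3)
        assert fit["p"] < 0.001

    def test_separation_flagged(self):
        with pytest.raises(SeparationError):
            fit_logistic_intercept(160, 160)
        with pytest.raises(SeparationError):
            fit_logistic_intercept(0, 160)

    def test_agrees_with_irls_intercept_only(self, rng):
        y = (rng.random(300) < 0.6).astype(float)
        closed = fit_logistic_intercept(int(y.sum()), y.size)
        irls = fit_logistic(y)
        assert closed["intercept"]["coef"] == pytest.approx(
            irls["intercept"]["coef"], abs=1e-8
        )
        assert closed["intercept"]["se"] == pytest.approx(
            irls["intercept"]["se"], abs=1e-6
        )


class TestLogistic:
    def test_two_by_two_log_odds_ratio(self):
        y = np.repeat([1, 0, 1, 0], [30, 10, 10, 30]).astype(float)
        x = np.repeat([0, 0, 1, 1], [30, 10, 10, 30]).astype(float)
        fit = fit_logistic(y, x, names=("intercept", "slope"))
        assert fit["slope"]["coef"] == pytest.approx(-np.log(9.0), abs=1e-6)

    def test_independent_predictor_slope_near_zero(self, rng):
        y = (rng.random(4000) < 0.5).astype(float)
        x = (rng.random(4000) < 0.5).astype(float)
        fit = fit_logistic(y, x)
        assert abs(fit["x1"]["coef"]) < 3 * fit["x1"]["se"]

    def test_constant_predictor_rank_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic(np.array([0, 1, 0, 1.0]), np.ones(4))

    def test_deviation_code_flip_negates_coefficient(self):
        y = np.repeat([1, 0, 1, 0], [30, 10, 15, 25]).astype(float)
        levels = np.repeat(["a", "a", "b", "b"], [30, 10, 15, 25])
        f = CodedFactor("g", {"a": 0.5, "b": -0.5})
        fit1 = fit_logistic(y, f.code(levels), names=("intercept", "g"))
        fit2 = fit_logistic(y, f.flipped().code(levels), names=("intercept", "g"))
        assert fit1["g"]["coef"] == pytest.approx(-fit2["g"]["coef"], abs=1e-9)
        assert fit1["intercept"]["coef"] == pytest.approx(
            fit2["intercept"]["coef"], abs=1e-9
        )


class TestRandomInterceptLogit:
    def test_recovery_without_heterogeneity(self, matcher_cohort):
        fit = fit_logit_glmm(matcher_cohort, "majority_order")
        i = fit["intercept"]
        assert abs(i["coef"] - logit(0.75)) < 3 * i["se"]
        assert fit.extra["random_effect_sd"] < 0.35

    def test_recovery_with_heterogeneity(self):
        t = gb.simulate_exp2_experiment(params=gb.matcher(sigma_u=0.8), seed=31)
        fit = fit_logit_glmm(t, "majority_order")
        i = fit["intercept"]
        assert abs(i["coef"] - logit(0.75)) < 3 * i["se"]
        sd, sd_se = fit.extra["random_effect_sd"], fit.extra["random_effect_sd_se"]
        assert abs(sd - 0.8) < 3 * sd_se

    def test_all_at_chance_gives_zero_intercept(self):
        rows = []
        import pandas as pd

        for pid in range(12):
            for j in range(16):
                rows.append(
                    {
                        "participant_id": f"p{pid}",
                        "phase": "test",
                        "condition": "natural descriptive",
                        "meaning_type": "descriptive",
                        "is_majority": j % 2 == 0,
                        "is_natural": j % 2 == 0,
                    }
                )
        t = pd.DataFrame(rows)
        fit = fit_logit_glmm(t, "majority_order")
        assert fit["intercept"]["coef"] == pytest.approx(0.0, abs=1e-4)

    def test_boundary_matches_pooled_logistic(self):
        """On underdispersed data the random-SD estimate collapses to the
        zero boundary and the marginal deviance equals plain logistic."""
        import pandas as pd

        rows = []
        for pid in range(30):
            for j in range(16):
                hit = j % 4 != 0  # every participant at exactly 12/16
                rows.append(
                    {
                        "participant_id": f"p{pid}",
                        "phase": "test",
                        "condition": "natural descriptive",
                        "meaning_type": "descriptive",
                        "is_majority": hit,
                        "is_natural": hit,
                    }
                )
        t = pd.DataFrame(rows)
        glmm = fit_logit_glmm(t, "majority_order")
        pooled = fit_logistic(t["is_majority"].astype(float).to_numpy())
        assert glmm.extra["random_effect_sd"] < 1e-3
        assert glmm.deviance == pytest.approx(pooled.deviance, abs=1e-4)

    def test_quadrature_refinement(self, matcher_cohort):
        X, y, g, _ = _glmm_design(matcher_cohort, "majority_order", ())
        e10 = RandomInterceptLogit(quad_nodes=10).fit(X, y, g)
        e30 = RandomInterceptLogit(quad_nodes=30).fit(X, y, g)
        assert np.allclose(e10.coef_, e30.coef_, atol=1e-3)
        assert abs(e10.random_effect_sd_ - e30.random_effect_sd_) < 1e-3

    def test_sklearn_param_interface(self):
        est = RandomInterceptLogit()
        assert est.get_params()["quad_nodes"] == 10
        est.set_params(quad_nodes=5)
        assert est.quad_nodes == 5
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_deviation_flip_negates_glmm_coefficient(self, mixture_cohort):
        X, y, g, names = _glmm_design(
            mixture_cohort, "majority_order", ("majority_natural",)
        )
        Xf = X.copy()
        Xf[:, 1] = -Xf[:, 1]
        a = RandomInterceptLogit().fit(X, y, g)
        b = RandomInterceptLogit().fit(Xf, y, g)
        assert a.coef_[1] == pytest.approx(-b.coef_[1], abs=1e-4)
        assert a.coef_[0] == pytest.approx(b.coef_[0], abs=1e-4)


class TestLikelihoodRatio:
    def test_identical_models(self, matcher_cohort):
        fit = fit_logit_glmm(matcher_cohort, "majority_order")
        full = fit_logit_glmm(matcher_cohort, "majority_order", ("majority_natural",))
        chi2, df, p = likelihood_ratio_test(fit, full)
        assert df == 1 and chi2 >= 0 and 0 <= p <= 1

    def test_mismatched_data_rejected(self, matcher_cohort, mixture_cohort):
        a = fit_logit_glmm(matcher_cohort, "majority_order")
        sub = mixture_cohort[
            mixture_cohort.participant_id.isin(
                mixture_cohort.participant_id.unique()[:100]
            )
        ]
        b = fit_logit_glmm(sub, "majority_order", ("majority_natural",))
        with pytest.raises(ValueError):
            likelihood_ratio_test(a, b)

    def test_type_i_error_calibration(self):
        """Adding a null predictor: LRT rejects at ~5% over 1,000
        simulated datasets."""
        rng = np.random.default_rng(12)
        rejections = 0
        n = 200
        x = np.repeat([0.5, -0.5], n // 2)
        for _ in range(1000):
            y = (rng.random(n) < 0.6).astype(float)
            null = fit_logistic(y)
            full = fit_logistic(y, x)
            _, _, p = likelihood_ratio_test(null, full)
            rejections += p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_strong_effect(self):
        rng = np.random.default_rng(13)
        x = np.repeat([0.5, -0.5], 100)
        hits = 0
        for _ in range(40):
            y = (rng.random(200) < expit(1.5 * x)).astype(float)
            _, _, p = likelihood_ratio_test(fit_logistic(y), fit_logistic(y, x))
            hits += p < 0.001
        assert hits >= 38


class TestOLSRating:
    def test_two_group_difference_in_means(self, rng):
        g = np.repeat([0.0, 1.0], 2000)
        y = np.where(g == 1, 76.0, 80.0) + 0.1 * rng.normal(size=4000)
        fit = fit_ols_rating(y, g)
        assert fit["predicted_order"]["coef"] == pytest.approx(-4.0, abs=0.05)
        assert fit.stat_label == "t"

    def test_identical_groups_coefficient_zero(self):
        y = np.tile([70.0, 80.0], 10)
        g = np.repeat([0.0, 1.0], 10)
        fit = fit_ols_rating(y, g)
        assert fit["predicted_order"]["coef"] == pytest.approx(0.0, abs=1e-10)

    def test_type_i_rate(self):
        rng = np.random.default_rng(14)
        g = np.repeat([0.0, 1.0], 50)
        rej = 0
        for _ in range(1000):
            y = 75 + 5 * rng.normal(size=100)
            rej += fit_ols_rating(y, g)["predicted_order"]["p"] < 0.05
        assert 0.03 <= rej / 1000 <= 0.07

    def test_collinear_design_rejected(self):
        y = np.arange(10.0)
        g = np.ones(10)
        with pytest.raises(Exception):
            fit_ols_rating(y, g, condition_codes=g, interaction=True)

    def test_interaction_requires_condition(self):
        with pytest.raises(ValueError):
            fit_ols_rating(np.arange(4.0), np.array([0, 1, 0, 1.0]), interaction=True)


def test_coded_factor_validation():
    with pytest.raises(ValueError):
        CodedFactor("bad", {"a": 1.0, "b": -1.0})
    assert MAJORITY_NATURAL_CODES.code([True, False]).tolist() == [0.5, -0.5]
    with pytest.raises(ValueError):
        MAJORITY_NATURAL_CODES.code(["oops"])
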