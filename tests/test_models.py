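"""Mixed models, repeatability and likelihood-ratio machinery, cross-checked
against closed forms, statsmodels and dense numerical integration."""

import numpy as np
import pandas as pd
import pytest

from boldtrack import models, synthetic
from boldtrack.models import (
    _Bernoulli,
    agq_loglik,
    fit_glm_binomial,
    fit_glmm_binomial,
    fit_lmm_random_intercept,
    fit_ordinal,
    laplace_loglik,
    lrt,
    repeatability,
    ssta_band,
)


def simulate_lmm(G, k, var_b, var_e, seed, beta0=0.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(G), k)
    y = beta0 + rng.normal(0, np.sqrt(var_b), G)[g] + rng.normal(0, np.sqrt(var_e), G * k)
    return y, np.ones((len(y), 1)), g


def simulate_glmm(G, k, sd, beta, seed):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(G), k)
    x = rng.normal(size=G * k)
    eta = beta[0] + beta[1] * x + rng.normal(0, sd, G)[g]
    y = (rng.random(G * k) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, np.column_stack([np.ones(G * k), x]), g


class TestLMM:
    def test_null_between_group_variance_shrinks_to_zero(self):
        y, X, g = simulate_lmm(200, 5, 0.0, 1.0, seed=0)
        fit = fit_lmm_random_intercept(y, X, g)
        assert fit.re_variances["group"] < 0.02

    def test_matches_statsmodels_mixedlm_ml(self):
        import statsmodels.api as sm
        y, X, g = simulate_lmm(60, 4, 0.8, 1.2, seed=1)
        fit = fit_lmm_random_intercept(y, X, g)
        sm_fit = sm.MixedLM(y, X, groups=g).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-5)
        assert fit.re_variances["group"] == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), abs=1e-4)
        assert fit.re_variances["residual"] == pytest.approx(float(sm_fit.scale), abs=1e-4)

    def test_balanced_design_near_anova_moment_estimator(self):
        """ML and the one-way ANOVA method-of-moments estimator agree up to
        the documented (G-1)/G factor on the between-group mean square."""
        G, k = 1000, 5
        y, X, g = simulate_lmm(G, k, 1.0, 1.0, seed=2)
        fit = fit_lmm_random_intercept(y, X, g)
        gm = y.reshape(G, k).mean(axis=1)
        msb = k * gm.var(ddof=1)
        msw = (y.reshape(G, k) - gm[:, None]).var(ddof=0) * G * k / (G * (k - 1))
        mom_b = (msb - msw) / k
        ml_equiv = ((G - 1) / G * msb - msw) / k  # exact balanced-design ML
        assert fit.re_variances["group"] == pytest.approx(ml_equiv, abs=1e-4)
        assert fit.re_variances["group"] == pytest.approx(mom_b, abs=5 * msb / (G * k))

    def test_variance_ratio_recovery(self):
        y, X, g = simulate_lmm(500, 3, 1.0, 1.0, seed=3)
        fit = fit_lmm_random_intercept(y, X, g)
        assert fit.re_variances["group"] == pytest.approx(1.0, rel=0.10)
        assert fit.re_variances["residual"] == pytest.approx(1.0, rel=0.10)

    def test_profile_gradient_vanishes_at_interior_optimum(self):
        from boldtrack.models import _lmm_profile
        y, X, g = simulate_lmm(100, 4, 1.0, 1.0, seed=4)
        fit = fit_lmm_random_intercept(y, X, g)
        lam = fit.extra["lambda"]
        assert lam > 0
        h = 1e-5
        up = _lmm_profile(y, X, fit._codes, 100, lam * (1 + h))[0]
        dn = _lmm_profile(y, X, fit._codes, 100, lam * (1 - h))[0]
        assert abs(up - dn) / (2 * h) < 1e-2  # d ll / d log-lambda ~ 0


class TestRepeatability:
    def test_r_is_variance_ratio(self):
        y, X, g = simulate_lmm(80, 3, 1.0, 1.0, seed=5)
        fit = fit_lmm_random_intercept(y, X, g)
        est = repeatability(fit, n_boot=0)
        vb, ve = fit.re_variances["group"], fit.re_variances["residual"]
        assert est.r == pytest.approx(vb / (vb + ve))
        assert 0.0 <= est.r <= 1.0

    def test_affine_invariance(self):
        y, X, g = simulate_lmm(80, 3, 1.0, 1.0, seed=6)
        r1 = repeatability(fit_lmm_random_intercept(y, X, g), n_boot=0).r
        r2 = repeatability(fit_lmm_random_intercept(3.0 * y - 7.0, X, g), n_boot=0).r
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_boundary_fit_reports_zero_with_ci_floor(self):
        y, X, g = simulate_lmm(100, 3, 0.0, 1.0, seed=7)
        fit = fit_lmm_random_intercept(y, X, g)
        est = repeatability(fit, n_boot=50, rng=0)
        if fit.re_variances["group"] == 0.0:
            assert est.r == 0.0 and est.ci[0] == 0.0

    def test_recovery_at_field_like_design(self):
        """~40 birds with 1-3 trips each, true r = 0.49: the mean estimate
        over replicates sits within +/-0.1."""
        rng = np.random.default_rng(8)
        ests = []
        for rep in range(10):
            sizes = rng.integers(1, 4, size=40)
            g = np.repeat(np.arange(40), sizes)
            b = rng.normal(0, np.sqrt(0.49 / 0.51), 40)
            y = b[g] + rng.normal(0, 1.0, len(g))
            fit = fit_lmm_random_intercept(y, np.ones((len(y), 1)), g)
            ests.append(repeatability(fit, n_boot=0).r)
        assert np.mean(ests) == pytest.approx(0.49, abs=0.1)

    def test_parametric_bootstrap_se_and_ci(self):
        y, X, g = simulate_lmm(60, 3, 1.0, 1.0, seed=9)
        fit = fit_lmm_random_intercept(y, X, g)
        est = repeatability(fit, n_boot=100, rng=1)
        assert est.se is not None and est.se > 0
        assert est.ci[0] <= est.r <= est.ci[1]


class TestGLMBinomial:
    def test_intercept_only_closed_form(self):
        y = np.concatenate([np.ones(30), np.zeros(70)])
        fit = fit_glm_binomial(y, np.ones((100, 1)))
        assert fit.params["x0"] == pytest.approx(np.log(3 / 7), abs=1e-8)

    def test_two_by_two_log_odds_ratio(self):
        # counts: x=0 -> 20 successes / 10 failures; x=1 -> 10 / 20
        y = np.concatenate([np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)])
        x = np.concatenate([np.zeros(30), np.ones(30)])
        fit = fit_glm_binomial(y, np.column_stack([np.ones(60), x]))
        assert fit.params["x1"] == pytest.approx(-np.log(4), abs=1e-6)

    def test_all_ones_is_separation(self):
        with pytest.raises(models.SeparationError):
            fit_glm_binomial(np.ones(20), np.ones((20, 1)))

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="rank"):
            fit_glm_binomial(np.r_[np.ones(5), np.zeros(5)], X)

    def test_lrt_invariant_to_covariate_centring(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        ones = np.ones(200)

        def chi2(xc):
            full = fit_glm_binomial(y, np.column_stack([ones, xc]))
            red = fit_glm_binomial(y, ones[:, None])
            return lrt(full, red).chi2

        assert chi2(x) == pytest.approx(chi2(x + 13.7), abs=1e-6)


class TestGLMMBinomial:
    def test_zero_variance_matches_glm(self):
        """With no true group variance the mixed fit degenerates to the
        GLM: same coefficients, and a log-likelihood no worse than the
        GLM's (the estimated variance may sit slightly off zero by
        sampling noise)."""
        y, X, g = simulate_glmm(50, 10, 0.0, (0.3, 0.8), seed=11)
        glm = fit_glm_binomial(y, X)
        glmm = fit_glmm_binomial(y, X, g)
        for k in glm.params:
            assert glmm.params[k] == pytest.approx(glm.params[k], abs=1e-2)
        assert glmm.loglik >= glm.loglik - 1e-6
        assert glmm.loglik == pytest.approx(glm.loglik, abs=0.5)
        assert glmm.re_variances["group"] < 0.1

    def test_agq_matches_dense_quadrature_oracle(self):
        """15-node adaptive quadrature agrees with 201-node integration to
        1e-3 on 20-group simulations."""
        for seed in (12, 13):
            y, X, g = simulate_glmm(20, 15, 1.0, (0.3, 0.8), seed=seed)
            fit = fit_glmm_binomial(y, X, g, n_quad=15)
            beta = np.array([fit.params["x0"], fit.params["x1"]])
            sd = np.sqrt(fit.re_variances["group"])
            dense = agq_loglik(_Bernoulli(), X @ beta, y, g, sd, n_nodes=201)
            assert fit.loglik == pytest.approx(dense, abs=1e-3)

    def test_laplace_close_to_quadrature_per_group(self):
        y, X, g = simulate_glmm(20, 50, 0.7, (0.2, 0.5), seed=14)
        beta = np.array([0.2, 0.5])
        sd = 0.7
        ll_q = agq_loglik(_Bernoulli(), X @ beta, y, g, sd, n_nodes=201)
        ll_l = laplace_loglik(_Bernoulli(), X @ beta, y, [g], [20], [sd])
        assert abs(ll_q - ll_l) / 20 < 1e-2

    def test_variance_recovery(self):
        ests = []
        for seed in range(15, 20):
            y, X, g = simulate_glmm(100, 20, 1.0, (0.0, 0.5), seed=seed)
            fit = fit_glmm_binomial(y, X, g)
            ests.append(fit.re_variances["group"])
        assert np.mean(ests) == pytest.approx(1.0, rel=0.30)

    def test_gradient_vanishes_at_optimum(self):
        y, X, g = simulate_glmm(30, 12, 0.8, (0.2, 0.6), seed=20)
        fit = fit_glmm_binomial(y, X, g)
        theta = np.array([fit.params["x0"], fit.params["x1"],
                          0.5 * np.log(fit.re_variances["group"])])

        def ll(t):
            return agq_loglik(_Bernoulli(), X @ t[:2], y, g, np.exp(t[2]))

        h = 1e-5
        grad = np.array([
            (ll(theta + h * e) - ll(theta - h * e)) / (2 * h)
            for e in np.eye(3)
        ])
        assert np.max(np.abs(grad)) < 0.05

    def test_crossed_factors_fit_runs(self):
        rng = np.random.default_rng(21)
        n = 600
        f1 = rng.integers(0, 30, n)
        f2 = rng.integers(0, 10, n)
        eta = 0.2 + rng.normal(0, 0.8, 30)[f1] + rng.normal(0, 0.5, 10)[f2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_glmm_binomial(y, np.ones((n, 1)), f1, groups2=f2)
        assert fit.n_params == 3
        assert np.isfinite(fit.loglik)
        assert fit.re_variances["group"] >= 0.0


class TestOrdinal:
    def test_null_model_thresholds_are_cumulative_logits(self):
        y = np.array([0] * 30 + [1] * 50 + [2] * 20)
        fit = fit_ordinal(y)
        from scipy.special import logit
        assert fit.params["threshold_1"] == pytest.approx(logit(0.3), abs=1e-5)
        assert fit.params["threshold_2"] == pytest.approx(logit(0.8), abs=1e-5)

    def test_binary_collapse_matches_logistic(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(0.2 + 0.9 * x)))).astype(int)
        ordfit = fit_ordinal(y, x[:, None], xnames=["x"])
        glm = fit_glm_binomial(y.astype(float), np.column_stack([np.ones(300), x]),
                               xnames=["intercept", "x"])
        # cumulative-logit parameterisation: P(y=1) = expit(eta - threshold)
        assert ordfit.params["x"] == pytest.approx(glm.params["x"], abs=1e-5)
        assert ordfit.params["threshold_1"] == pytest.approx(
            -glm.params["intercept"], abs=1e-5)
        assert ordfit.loglik == pytest.approx(glm.loglik, abs=1e-6)

    def test_matches_statsmodels_ordered_model(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        rng = np.random.default_rng(23)
        x = rng.normal(size=400)
        eta = 0.8 * x
        cuts = np.array([-0.5, 0.7])
        u = rng.logistic(size=400)
        y = (eta + u > cuts[0]).astype(int) + (eta + u > cuts[1]).astype(int)
        fit = fit_ordinal(y, x[:, None], xnames=["x"])
        sm_fit = OrderedModel(y, x[:, None], distr="logit").fit(method="bfgs", disp=0)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
        assert fit.params["x"] == pytest.approx(sm_fit.params[0], abs=1e-3)

    def test_slope_sign_recovery_with_random_intercept(self):
        rng = np.random.default_rng(24)
        G, k = 40, 6
        g = np.repeat(np.arange(G), k)
        x = rng.normal(size=G * k)
        eta = 1.2 * x + rng.normal(0, 0.7, G)[g]
        u = rng.logistic(size=G * k)
        y = (eta + u > -0.8).astype(int) + (eta + u > 0.8).astype(int)
        fit = fit_ordinal(y, x[:, None], groups=g, xnames=["x"])
        assert fit.params["x"] > 0
        assert fit.re_variances["group"] >= 0

    def test_single_observed_category_rejected(self):
        with pytest.raises(ValueError, match="2 observed"):
            fit_ordinal(np.zeros(20, dtype=int))


class TestLRT:
    def test_identical_models_give_zero(self):
        y = np.concatenate([np.ones(30), np.zeros(30)])
        f = fit_glm_binomial(y, np.ones((60, 1)))
        g = models.ModelFit(family="binomial", params={}, loglik=f.loglik,
                            n_params=f.n_params + 1, nobs=f.nobs)
        res = lrt(g, f)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_row_count_mismatch_rejected(self):
        a = models.ModelFit("binomial", {}, -10.0, 2, 100)
        b = models.ModelFit("binomial", {}, -11.0, 1, 99)
        with pytest.raises(ValueError, match="row-count"):
            lrt(a, b)

    def test_non_nested_rejected(self):
        a = models.ModelFit("binomial", {}, -10.0, 2, 100)
        b = models.ModelFit("binomial", {}, -11.0, 2, 100)
        with pytest.raises(ValueError, match="not nested"):
            lrt(a, b)


class TestSSTaBands:
    @pytest.mark.parametrize("value,band", [
        (-0.5, "low"), (-0.2, "medium"), (0.0, "high"),
        (-0.36, "medium"), (-0.15, "high"),
    ])
    def test_tercile_banding(self, value, band):
        assert ssta_band(value) == band


@pytest.fixture(scope="module")
def planted():
    cfg = synthetic.SimConfig(
        seed=30, n_birds=59,
        fledging_effects=synthetic.FledgingEffects(
            intercept=0.3, score=0.3, ssta=0.8, score_sex=-0.6))
    rng = np.random.default_rng(31)
    idx = [f"bird{b:03d}" for b in range(cfg.n_birds)]
    scores = pd.Series(rng.normal(0, 1.3, cfg.n_birds), index=idx)
    scores -= scores.mean()
    breeding, ssta, _ = synthetic.simulate_breeding(cfg, scores)
    return breeding, scores, ssta.set_index("year")["ssta"]


class TestFitnessAnalysis:

    def test_interaction_test_is_four_df(self, planted):
        breeding, scores, ssta = planted
        res = models.fitness_analysis(breeding, scores, ssta)
        assert res["interaction_test"].df == 4
        assert res["full"].n_params - res["reduced"].n_params == 4
        assert res["interaction_test"].chi2 >= 0.0

    def test_missing_ssta_year_is_informative_error(self, planted):
        breeding, scores, ssta = planted
        with pytest.raises(ValueError, match="SSTa.*year"):
            models.fitness_analysis(breeding, scores, ssta.drop(2011))

    def test_prediction_curves_are_probabilities_by_band_and_sex(self, planted):
        breeding, scores, ssta = planted
        res = models.fitness_analysis(breeding, scores, ssta)
        curves = models.prediction_curves(res["full"])
        assert set(curves["band"]) == {"low", "medium", "high"}
        assert set(curves["sex"]) == {"female", "male"}
        assert curves["p_fledge"].between(0, 1).all()

    def test_single_year_analysis(self, planted):
        breeding, scores, _ = planted
        year0 = breeding[breeding["year"] == 2011]
        res = models.single_year_fitness(year0, scores)
        assert res["score"].df == 1 and res["score:sex"].df == 1
        assert res["score"].chi2 >= 0
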