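"""GLM/GLMM machinery: IRLS, Laplace marginal likelihood, prediction, AIC."""

import numpy as np
import pandas as pd
import pytest

from meadowmrr._numeric import invlogit
from meadowmrr.glmm import (
    FAMILIES,
    EstimationError,
    GLMMFit,
    ModelSpec,
    _irls,
    aic_select,
    apply_scaling,
    fit_glm,
    fit_glmm,
    glmm_marginal_loglik,
    predict_response,
    scale_covariates,
    unscale,
)


def bernoulli_frame(rng, n, eta_fn, localities=5):
    loc = rng.integers(0, localities, n)
    x = rng.normal(0.0, 1.0, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    regime = rng.choice(["unmown", "recovered", "mown"], size=n)
    eta = eta_fn(x, sex, regime, loc)
    y = (rng.random(n) < invlogit(eta)).astype(int)
    return pd.DataFrame(
        {"y": y, "x": x, "sex": sex, "regime": regime, "locality": [f"L{i}" for i in loc]}
    )


class TestScaling:
    def test_scaled_columns_are_standardised(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": list("xyzw")})
        out, record = scale_covariates(df, ["a"])
        assert out["a"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["a"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)
        back = unscale(out["a"].to_numpy(), "a", record)
        assert np.allclose(back, df["a"], atol=1e-12)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            scale_covariates(df, ["a"])

    def test_apply_scaling_matches_fit_scaling(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 9.0]})
        scaled, record = scale_covariates(df, ["a"])
        again = apply_scaling(pd.DataFrame({"a": [5.0]}), record)
        assert again["a"].iloc[0] == pytest.approx(scaled["a"].iloc[1])


class TestGLM:
    def test_binomial_intercept_only_matches_proportion(self):
        y = np.array([1] * 13 + [0] * 27)
        fit = fit_glm(ModelSpec("binomial", "y"), pd.DataFrame({"y": y}))
        assert invlogit(fit.coef[0]) == pytest.approx(13 / 40, abs=1e-9)

    def test_gamma_intercept_only_matches_mean(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(2.0, 30.0, size=200)
        fit = fit_glm(ModelSpec("gamma", "y"), pd.DataFrame({"y": y}))
        assert np.exp(fit.coef[0]) == pytest.approx(y.mean(), rel=1e-8)
        assert fit.dispersion == pytest.approx(2.0, rel=0.3)

    def test_poisson_matches_reference_implementation(self):
        import statsmodels.api as sm

        df = pd.DataFrame(
            {
                "y": [2, 5, 1, 7, 3, 4],
                "x": [0.1, 0.9, -0.4, 1.4, 0.3, 0.7],
                "g": ["a", "b", "a", "b", "a", "b"],
            }
        )
        fit = fit_glm(ModelSpec("poisson", "y", ("x", "g")), df)
        X = pd.DataFrame({"c": 1.0, "x": df.x, "g": (df.g == "b").astype(float)})
        ref = sm.GLM(df.y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(fit.coef - ref.params.values)) < 1e-6
        assert np.max(np.abs(fit.se - ref.bse.values)) < 1e-6
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_irls_loglik_is_monotone(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(0, 1, n)
        y = rng.poisson(np.exp(0.5 + 0.8 * x))
        X = np.column_stack([np.ones(n), x])
        trace = []
        _irls(FAMILIES["poisson"], X, y.astype(float), trace=trace)
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_rank_deficiency_names_offender(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(EstimationError, match="rank"):
            fit_glm(ModelSpec("gaussian", "y", ("a", "b")), df)


class TestGLMM:
    def test_zero_variance_reduces_to_glm(self):
        rng = np.random.default_rng(4)
        df = bernoulli_frame(rng, 600, lambda x, s, r, g: -0.4 + 0.8 * x)
        glm = fit_glm(ModelSpec("binomial", "y", ("x",)), df)
        glmm = fit_glmm(ModelSpec("binomial", "y", ("x",), group="locality"), df)
        assert glmm.boundary
        assert np.max(np.abs(glmm.coef - glm.coef)) < 1e-4
        assert glmm.loglik == pytest.approx(glm.loglik, abs=1e-6)

    def test_laplace_close_to_adaptive_quadrature(self):
        rng = np.random.default_rng(5)
        df = bernoulli_frame(
            rng, 250, lambda x, s, r, g: -0.5 + 0.9 * x + 0.6 * rng.standard_normal(5)[g]
        )
        spec = ModelSpec("binomial", "y", ("x",), group="locality")
        fit = fit_glmm(spec, df)
        assert fit.re_variance > 0
        fam = FAMILIES["binomial"]
        X, _ = fit.design.build(df)
        y = df["y"].to_numpy(float)
        groups = df["locality"].to_numpy()
        args = (fam, X, y, groups, fit.coef, np.sqrt(fit.re_variance), None)
        ll_lap = glmm_marginal_loglik(*args, method="laplace")
        ll_agq = glmm_marginal_loglik(*args, method="agq", agq_nodes=25)
        assert abs(ll_lap - ll_agq) < 0.05

    def test_recovers_sex_coefficient_from_emigration_style_data(self):
        """Binomial mixed model on data generated with the emigration
        analysis' coefficient structure recovers the sex effect."""
        rng = np.random.default_rng(6)
        true_sex_male = -0.694
        effects = {"unmown": 0.0, "recovered": 0.574, "mown": 0.974}
        loc_effect = 0.3 * rng.standard_normal(5)

        def eta(x, sex, regime, loc):
            return (
                -1.907
                + np.vectorize(effects.get)(regime)
                + true_sex_male * (sex == "M")
                + loc_effect[loc]
            )

        df = bernoulli_frame(rng, 1200, eta)
        fit = fit_glmm(
            ModelSpec("binomial", "y", ("regime", "sex"), group="locality"), df
        )
        i = fit.names.index("sex[M]")
        assert fit.coef[i] == pytest.approx(true_sex_male, abs=3 * fit.se[i])
        # predicted emigration ordering follows the regime effects
        newdata = pd.DataFrame(
            {"regime": ["mown", "recovered", "unmown"], "sex": ["F", "F", "F"]}
        )
        mu, _ = predict_response(fit, newdata)
        assert mu[0] > mu[1] > mu[2]


class TestPrediction:
    def test_intercept_only_prediction_is_proportion(self):
        y = np.array([1] * 9 + [0] * 21)
        fit = fit_glm(ModelSpec("binomial", "y"), pd.DataFrame({"y": y}))
        mu, se = predict_response(fit, pd.DataFrame(index=[0]))
        assert mu[0] == pytest.approx(0.3, abs=1e-9)
        # analytic SE of a proportion
        assert se[0] == pytest.approx(np.sqrt(0.3 * 0.7 / 30), rel=1e-6)

    def test_delta_method_se_close_to_parametric_bootstrap(self):
        rng = np.random.default_rng(7)
        n = 150
        y = (rng.random(n) < 0.35).astype(int)
        df = pd.DataFrame({"y": y})
        fit = fit_glm(ModelSpec("binomial", "y"), df)
        mu, se = predict_response(fit, pd.DataFrame(index=[0]))
        boots = []
        for _ in range(1000):
            yb = (rng.random(n) < mu[0]).astype(int)
            fb = fit_glm(ModelSpec("binomial", "y"), pd.DataFrame({"y": yb}))
            mb, _ = predict_response(fb, pd.DataFrame(index=[0]))
            boots.append(mb[0])
        assert se[0] == pytest.approx(np.std(boots), rel=0.15)

    def test_unseen_factor_level_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "g": ["a", "b", "a", "b"]})
        fit = fit_glm(ModelSpec("gaussian", "y", ("g",)), df)
        with pytest.raises(ValueError, match="unseen"):
            predict_response(fit, pd.DataFrame({"g": ["c"]}))

    def test_scaled_covariates_are_transparent_to_prediction(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(100, 1000, 200)
        y = rng.gamma(2.0, np.exp(3.0 + 0.001 * x) / 2.0)
        df = pd.DataFrame({"y": y, "x": x})
        fit = fit_glm(ModelSpec("gamma", "y", ("x",), scale=("x",)), df)
        mu, _ = predict_response(fit, pd.DataFrame({"x": [500.0]}))
        assert np.isfinite(mu[0]) and mu[0] > 0


class TestSelection:
    def _fit(self, label, aic, k):
        f = GLMMFit.__new__(GLMMFit)
        f.spec = ModelSpec("gaussian", "y", name=label)
        f.names = ["(Intercept)"] * k
        f.coef = np.zeros(k)
        f.aic = aic
        f.converged = True
        return f

    def test_lowest_aic_wins(self):
        a, b = self._fit("a", 100.0, 3), self._fit("b", 105.0, 3)
        assert aic_select([a, b]) is a

    def test_simpler_model_within_two_units(self):
        a, b = self._fit("big", 100.0, 5), self._fit("small", 101.5, 3)
        assert aic_select([a, b]) is b

    def test_exact_tie_equal_k_lexicographic(self):
        a, b = self._fit("zeta", 100.0, 3), self._fit("alpha", 100.0, 3)
        assert aic_select([a, b]) is b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aic_select([])
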