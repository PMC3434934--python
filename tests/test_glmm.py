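import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special

from anurainvade.glmm import (ConvergenceWarning, FitResult, LaplaceGLMM,
                              RandomStructure, aicc, build_design,
                              build_random_terms, fit_glmm,
                              predict_probability)


class TestAicc:
    def test_hand_value(self):
        assert aicc(-10, 2, 100) == pytest.approx(24.1237, abs=5e-5)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10, 2, 10**9) == pytest.approx(24.0, abs=1e-6)

    def test_domain_boundary(self):
        aicc(-1, 1, 3)  # n - k - 1 = 1: allowed
        with pytest.raises(ValueError):
            aicc(-1, 1, 2)


class TestDesign:
    def test_intentionality_dummies_reference_intentional(self, small_tables):
        _, sd3 = small_tables
        X, labels = build_design(sd3, ["intentionality", "climate_match"])
        assert labels[0] == "(Intercept)"
        assert "intentionality[unintentional]" in labels
        assert "intentionality[unknown]" in labels
        assert not any("intentional]" == l.split("[")[-1] for l in labels)
        assert X.shape[1] == len(labels)

    def test_factor_codes_accepted(self, small_tables):
        _, sd3 = small_tables
        X, labels = build_design(sd3, [8, 7])
        assert labels == ["(Intercept)", "island", "climate_match"]

    def test_nested_terms_use_composite_keys(self):
        tab = pd.DataFrame({
            "family": ["F1", "F1", "F2", "F2"],
            "genus": ["G1", "G1", "G1", "G2"],  # label G1 reused across families
            "species": ["a", "b", "c", "d"],
            "location": ["L1", "L2", "L1", "L2"],
        })
        terms = build_random_terms(tab, RandomStructure())
        by_label = {t.label: t for t in terms}
        assert by_label["family:genus"].n_levels == 3  # F1:G1, F2:G1, F2:G2


class TestFitAgainstGLMOracle:
    def test_zero_variance_matches_irls_glm(self, small_tables):
        """With every random SD pinned at 0 the mixed fit must agree with
        an ordinary logit GLM to 1e-6."""
        _, sd3 = small_tables
        factors = ["climate_match", "island", "intentionality"]
        zero = {lbl: 0.0 for lbl in RandomStructure().labels}
        fit = fit_glmm(sd3, factors, RandomStructure(), fixed_sds=zero)
        X, labels = build_design(sd3, factors)
        glm = sm.GLM(sd3["outcome"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef.to_numpy(), glm.params, atol=1e-6)
        np.testing.assert_allclose(fit.loglik, glm.llf, atol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), glm.bse, rtol=1e-4)


def adaptive_gauss_hermite_loglik(y, groups, beta0, sd, n_nodes=25):
    """Independent oracle: exact (to quadrature accuracy) marginal
    log-likelihood of an intercept + one-random-intercept logit model."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for g in np.unique(groups):
        yg = y[groups == g]

        def h(u):
            eta = beta0 + u
            return float(np.sum(yg * eta - np.logaddexp(0, eta))
                         - 0.5 * u**2 / sd**2 - 0.5 * np.log(2 * np.pi * sd**2))

        # scalar Newton for the mode of the integrand
        u = 0.0
        for _ in range(50):
            mu = special.expit(beta0 + u)
            grad = float(np.sum(yg - mu)) - u / sd**2
            hess = -float(np.sum(mu * (1 - mu))) - 1 / sd**2
            step = -grad / hess
            u += step
            if abs(step) < 1e-12:
                break
        scale = 1.0 / np.sqrt(-hess)
        z = u + np.sqrt(2.0) * scale * nodes
        vals = np.array([h(zi) for zi in z])
        total += np.log(np.sqrt(2.0) * scale
                        * np.sum(weights * np.exp(vals + nodes**2)))
    return total


class TestLaplaceAgainstQuadrature:
    def test_two_group_toy_loglik_within_005(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(["g1", "g2"], 5)
        y = rng.integers(0, 2, size=10).astype(float)
        beta0, sd = 0.3, 0.8
        tab = pd.DataFrame({"g": groups})
        terms = build_random_terms(tab, RandomStructure(nested=(), crossed=("g",)))
        prob = LaplaceGLMM(np.ones((10, 1)), y, terms)
        laplace = prob.loglik(np.array([beta0]), np.array([sd]))
        exact = adaptive_gauss_hermite_loglik(y, groups, beta0, sd)
        assert laplace == pytest.approx(exact, abs=0.05)


class TestFitBehaviour:
    def test_intercept_only_on_balanced_unstructured_data(self):
        rng = np.random.default_rng(17)
        n = 400
        tab = pd.DataFrame({
            "outcome": rng.integers(0, 2, size=n),
            "family": rng.choice([f"F{i}" for i in range(5)], n),
            "genus": rng.choice([f"G{i}" for i in range(12)], n),
            "species": rng.choice([f"S{i}" for i in range(40)], n),
            "location": rng.choice([f"L{i}" for i in range(20)], n),
        })
        fit = fit_glmm(tab, (), RandomStructure())
        b0, se0 = fit.coef["(Intercept)"], fit.se["(Intercept)"]
        assert abs(b0) < 3 * se0

    def test_loglik_monotone_in_nesting(self, small_tables):
        _, sd3 = small_tables
        lls = []
        for spec in [(), ("climate_match",), ("climate_match", "island"),
                     ("climate_match", "island", "intentionality")]:
            lls.append(fit_glmm(sd3, spec).loglik)
        diffs = np.diff(lls)
        assert np.all(diffs > -1e-4)

    def test_k_counts_fixed_plus_variance_components(self, small_tables):
        _, sd3 = small_tables
        fit = fit_glmm(sd3, ["climate_match", "intentionality"])
        # intercept + climate + 2 dummies = 4 fixed, 4 variance components
        assert fit.k == 8
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n))
        assert (fit.variance_components["variance"] >= 0).all()

    def test_separation_warning(self):
        n = 60
        x = np.r_[np.zeros(30), np.ones(30)]
        tab = pd.DataFrame({
            "outcome": x.astype(int), "climate_match": x - 0.5,
            "family": "F1", "genus": "G1",
            "species": [f"S{i}" for i in range(n)],
            "location": [f"L{i % 6}" for i in range(n)],
        })
        with pytest.warns(ConvergenceWarning, match="separation"):
            fit_glmm(tab, ["climate_match"])


def _dummy_fit(coef: dict) -> FitResult:
    s = pd.Series(coef)
    spec = tuple(k.split("[")[0] for k in coef if k != "(Intercept)")
    return FitResult(model_spec=tuple(dict.fromkeys(spec)), coef=s,
                     se=s * 0, variance_components=pd.DataFrame(),
                     loglik=0.0, k=len(s), n=100, aicc=0.0, converged=True)


class TestPredictProbability:
    def test_all_zero_coefficients_give_half(self):
        fit = _dummy_fit({"(Intercept)": 0.0, "climate_match": 0.0})
        assert predict_probability(fit, {"climate_match": 1.0}) == 0.5

    def test_large_linear_predictor_saturates(self):
        fit = _dummy_fit({"(Intercept)": 0.0, "climate_match": 20.0})
        assert predict_probability(fit, {"climate_match": 1.0}) > 0.9999

    def test_hand_inverse_logit(self):
        fit = _dummy_fit({"(Intercept)": 0.4055})
        assert predict_probability(fit, {}) == pytest.approx(0.6, abs=1e-4)

    def test_missing_covariate_rejected(self):
        fit = _dummy_fit({"(Intercept)": 0.0, "climate_match": 1.0})
        with pytest.raises(KeyError):
            predict_probability(fit, {})

    def test_categorical_reference_level(self):
        fit = _dummy_fit({"(Intercept)": 0.0,
                          "intentionality[unintentional]": -2.0})
        p_ref = predict_probability(fit, {"intentionality": "intentional"})
        p_un = predict_probability(fit, {"intentionality": "unintentional"})
        assert p_ref == 0.5 and p_un == pytest.approx(special.expit(-2.0))
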