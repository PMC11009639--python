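"""Point estimators: hand-evaluated cases, oracle equivalences, identities."""

import numpy as np
import pytest
from scipy.optimize import minimize

from crosspred import (ConstantLearner, LinearLearner, assign_folds,
                       classical_estimate, crosspred_glm, crosspred_mean,
                       crosspred_ols, crosspred_quantile, fit_crossfit,
                       heuristic_no_debias, heuristic_no_folds, make_estimand,
                       ppi_estimate)
from crosspred.estimands import UnsupportedOperationError
from crosspred.estimators import grad_Lplus
from crosspred.synthetic_data import DGPConfig, generate_mean_dgp

from conftest import make_constant_bundle


class TestCrosspredMean:
    def test_hand_evaluation_two_constant_models(self):
        """f1 = 2, f2 = 3 on Y=(1,2,3,4): imputation term 2.5, debias term 0."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.zeros((4, 1))
        Xu = np.zeros((2, 1))
        folds = assign_folds(4, 2, seed=0)
        # place outcomes so the constant-2 model debiases on (1,2) and the
        # constant-3 model on (3,4)
        y_arranged = np.empty(4)
        y_arranged[folds.indices(0)] = [1.0, 2.0]
        y_arranged[folds.indices(1)] = [3.0, 4.0]
        bundle = make_constant_bundle(y_arranged, [2.0, 3.0], X, Xu, seed=0)
        est = crosspred_mean(bundle, y_arranged)
        assert est.theta[0] == pytest.approx(2.5, abs=1e-12)

    def test_constant_predictor_collapses_to_sample_mean(self, rng):
        y = rng.normal(size=17)
        bundle = make_constant_bundle(y, [5.0] * 3, np.zeros((17, 1)),
                                      np.zeros((8, 1)))
        assert crosspred_mean(bundle, y).theta[0] == pytest.approx(y.mean(), abs=1e-14)

    def test_perfect_oof_predictions_leave_imputation_term(self, rng):
        y = rng.normal(size=10)
        Xu = np.zeros((5, 1))
        folds = assign_folds(10, 2, seed=0)
        unl = rng.normal(size=(2, 5))
        from crosspred import CrossFitBundle
        bundle = CrossFitBundle(models=[None, None], folds=folds, oof_pred=y.copy(),
                                unl_pred=unl, unl_pred_avg=unl.mean(axis=0))
        assert crosspred_mean(bundle, y).theta[0] == pytest.approx(
            unl.mean(), abs=1e-14)

    def test_matches_quadratic_vertex_of_debiased_loss(self, rng):
        """Squared-loss special case of the general debiased objective."""
        data = generate_mean_dgp(DGPConfig(n=30, N=50, r=0.5, seed=8))
        bundle = fit_crossfit(data.X, data.y, data.X_unlabeled,
                              assign_folds(30, 3, seed=8), LinearLearner())

        def Lplus(t):
            unl = ((bundle.unl_pred - t) ** 2).mean()
            debias = ((bundle.oof_pred - t) ** 2 - (data.y - t) ** 2).mean()
            return unl - debias

        # L+ is an exact quadratic: recover its vertex from three evaluations
        t0, t1, t2 = 0.0, 1.0, 2.0
        a = (Lplus(t2) - 2 * Lplus(t1) + Lplus(t0)) / 2
        b = (Lplus(t2) - Lplus(t0)) / 2 - 2 * a * t1
        vertex = -b / (2 * a)
        assert crosspred_mean(bundle, data.y).theta[0] == pytest.approx(
            vertex, abs=1e-10)


class TestCrosspredQuantile:
    def test_constant_predictor_reduces_to_empirical_quantile(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        bundle = make_constant_bundle(y, [2.5, 2.5], np.zeros((4, 1)),
                                      np.zeros((6, 1)))
        est = crosspred_quantile(bundle, y, q=0.75)
        assert est.theta[0] == pytest.approx(3.0)

    def test_left_tail(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        bundle = make_constant_bundle(y, [2.5, 2.5], np.zeros((4, 1)),
                                      np.zeros((6, 1)))
        est = crosspred_quantile(bundle, y, q=1e-9)
        corrected = est.cdf.corrected
        first_pos = est.cdf.grid[np.flatnonzero(corrected > 0)[0]]
        assert est.theta[0] == pytest.approx(first_pos)

    def test_perfect_predictor_large_N_near_true_quantile(self):
        """R^2=1 with a correctly specified learner: imputations are exact."""
        data = generate_mean_dgp(DGPConfig(n=200, N=20_000, r=1.0, seed=6))
        bundle = fit_crossfit(data.X, data.y, data.X_unlabeled,
                              assign_folds(200, 5, seed=6), LinearLearner())
        est = crosspred_quantile(bundle, data.y, q=0.75)
        # true 75th percentile of N(4, 4) = 5.3490; MC error ~ sigma/sqrt(N)
        assert est.theta[0] == pytest.approx(5.3490, abs=0.1)


class TestCrosspredOLS:
    def test_zero_predictor_hand_case(self):
        y = np.array([1.0, 3.0])
        X = np.ones((2, 1))
        Xu = np.ones((2, 1))
        bundle = make_constant_bundle(y, [0.0, 0.0], X, Xu)
        est = crosspred_ols(bundle, X, y, Xu)
        assert est.theta[0] == pytest.approx(2.0, abs=1e-12)

    def test_oof_equals_y_reduces_to_imputed_least_squares(self, rng):
        n, N = 12, 20
        X = rng.normal(size=(n, 2))
        Xu = rng.normal(size=(N, 2))
        y = rng.normal(size=n)
        unl = rng.normal(size=(2, N))
        from crosspred import CrossFitBundle
        bundle = CrossFitBundle(models=[None] * 2, folds=assign_folds(n, 2, 0),
                                oof_pred=y.copy(), unl_pred=unl,
                                unl_pred_avg=unl.mean(axis=0))
        est = crosspred_ols(bundle, X, y, Xu)
        direct, *_ = np.linalg.lstsq(Xu, unl.mean(axis=0), rcond=None)
        np.testing.assert_allclose(est.theta, direct, atol=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_closed_form_equals_numeric_minimizer(self, seed):
        """Independent oracle: numeric minimization of the debiased loss."""
        rng = np.random.default_rng(seed)
        n, N, d = 20, 40, 2
        X = rng.normal(size=(n, d))
        Xu = rng.normal(size=(N, d))
        y = X @ [1.0, -0.5] + rng.normal(size=n)
        bundle = fit_crossfit(X, y, Xu, assign_folds(n, 4, seed), LinearLearner())

        def Lplus(t):
            unl = (0.5 * (bundle.unl_pred - Xu @ t) ** 2).mean()
            lab = (0.5 * (bundle.oof_pred - X @ t) ** 2
                   - 0.5 * (y - X @ t) ** 2).mean()
            return unl - lab

        res = minimize(Lplus, np.zeros(d), method="BFGS",
                       options={"gtol": 1e-12})
        est = crosspred_ols(bundle, X, y, Xu)
        np.testing.assert_allclose(est.theta, res.x, atol=1e-6)
        grad = grad_Lplus(bundle, X, y, Xu, make_estimand("ols", d=d), est.theta)
        assert np.linalg.norm(grad) < 1e-8


class TestCrosspredGLM:
    @pytest.mark.parametrize("seed", range(10))
    def test_identity_link_agrees_with_ols(self, seed):
        rng = np.random.default_rng(seed + 100)
        n, N, d = 25, 50, 2
        X = rng.normal(size=(n, d))
        Xu = rng.normal(size=(N, d))
        y = X @ [0.5, 1.5] + rng.normal(size=n)
        bundle = fit_crossfit(X, y, Xu, assign_folds(n, 5, seed), LinearLearner())
        est_ols = crosspred_ols(bundle, X, y, Xu)
        est_glm = crosspred_glm(bundle, X, y, Xu,
                                make_estimand("glm", d=d, link="identity"))
        np.testing.assert_allclose(est_glm.theta, est_ols.theta, atol=1e-8)

    def test_constant_half_predictor_intercept_model_gives_logit_of_mean(self, rng):
        """With f = 1/2 and an intercept-only design, the debiased score
        reduces to psi'(theta) = mean(y), i.e. theta = logit(ybar)."""
        n, N = 40, 60
        y = rng.uniform(0.2, 0.8, size=n)
        X = np.ones((n, 1))
        Xu = np.ones((N, 1))
        bundle = make_constant_bundle(y, [0.5, 0.5], X, Xu)
        est = crosspred_glm(bundle, X, y, Xu,
                            make_estimand("glm", d=1, link="logistic"))
        ybar = y.mean()
        assert est.theta[0] == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-7)

    def test_solver_contract_residual_gradient(self, rng):
        n, N, d = 60, 120, 3
        X = rng.normal(size=(n, d))
        Xu = rng.normal(size=(N, d))
        p = 1.0 / (1.0 + np.exp(-(X @ [0.4, -0.2, 0.1])))
        y = rng.binomial(1, p).astype(float)
        bundle = fit_crossfit(X, y, Xu, assign_folds(n, 4, seed=0), LinearLearner())
        est = crosspred_glm(bundle, X, y, Xu,
                            make_estimand("glm", d=d, link="logistic"))
        assert est.diagnostics["grad_norm"] <= 1e-8


class TestClassical:
    def test_mean_and_quantile(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert classical_estimate(None, y, make_estimand("mean")).theta[0] == 2.5
        assert classical_estimate(None, y,
                                  make_estimand("quantile", q=0.75)).theta[0] == 3.0

    def test_collinear_design_raises(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        y = np.arange(10, dtype=float)
        with pytest.raises(np.linalg.LinAlgError):
            classical_estimate(X, y, make_estimand("ols", d=2))


class TestPPI:
    def test_constant_model_gives_heldout_label_mean(self):
        """With a constant model the imputation and bias terms cancel."""
        rng = np.random.default_rng(0)
        n = 40
        X = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        Xu = rng.normal(size=(30, 2))
        est, bundle, held = ppi_estimate(X, y, Xu, make_estimand("mean"),
                                         0.5, ConstantLearner(2.0), seed=1)
        assert est.theta[0] == pytest.approx(y[held].mean(), abs=1e-12)

    def test_hand_evaluation(self):
        """n=4, constant-2 model: theta = 2 - mean(2 - y_held)."""
        X = np.zeros((4, 1))
        y = np.array([1.0, 2.0, 3.0, 4.0])
        Xu = np.zeros((5, 1))
        est, _, held = ppi_estimate(X, y, Xu, make_estimand("mean"), 0.5,
                                    ConstantLearner(2.0), seed=3)
        expected = 2.0 - (2.0 - y[held]).mean()
        assert est.theta[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(y[held].mean())

    def test_degenerate_split_raises(self):
        with pytest.raises(ValueError):
            ppi_estimate(np.zeros((4, 1)), np.arange(4.0), np.zeros((3, 1)),
                         make_estimand("mean"), 0.9, ConstantLearner(0.0), seed=0)


class TestHeuristics:
    def test_no_debias_keeps_constant_bias(self, rng):
        y = rng.normal(size=10)
        bundle = make_constant_bundle(y, [7.0, 7.0], np.zeros((10, 1)),
                                      np.zeros((4, 1)))
        est = heuristic_no_debias(bundle, make_estimand("mean"))
        assert est.theta[0] == pytest.approx(7.0)

    def test_no_debias_quantile_unsupported(self, rng):
        y = rng.normal(size=10)
        bundle = make_constant_bundle(y, [1.0, 1.0], np.zeros((10, 1)),
                                      np.zeros((4, 1)))
        with pytest.raises(UnsupportedOperationError):
            heuristic_no_debias(bundle, make_estimand("quantile", q=0.5))

    def test_no_folds_constant_learner_gives_sample_mean(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        Xu = rng.normal(size=(20, 2))
        est, _ = heuristic_no_folds(X, y, Xu, make_estimand("mean"),
                                    ConstantLearner(3.0), seed=0)
        assert est.theta[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_no_folds_unbiased_on_linear_dgp(self):
        """Monte-Carlo: average estimate within 3 SEs of the true mean."""
        rng = np.random.default_rng(42)
        estimates = []
        for t in range(300):
            data = generate_mean_dgp(DGPConfig(n=50, N=500, r=0.8, seed=int(rng.integers(2**31))))
            est, _ = heuristic_no_folds(data.X, data.y, data.X_unlabeled,
                                        make_estimand("mean"), LinearLearner(),
                                        seed=t)
            estimates.append(est.theta[0])
        estimates = np.asarray(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert estimates.mean() == pytest.approx(4.0, abs=3 * se + 1e-9)
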