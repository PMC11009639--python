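"""Bootstrap covariance estimation and the sandwich assembly."""

import numpy as np
import pytest

from crosspred import (BootstrapBundle, ConstantLearner, LinearLearner,
                       assemble_sandwich, estimate_hessian,
                       estimate_sigma_delta, estimate_sigma_theta,
                       fit_bootstrap_models, make_estimand)
from crosspred.synthetic_data import DGPConfig, generate_mean_dgp


def _toy_boot(pred_lab, pred_unl, holdouts):
    pred_lab = np.atleast_2d(np.asarray(pred_lab, dtype=float))
    pred_unl = np.atleast_2d(np.asarray(pred_unl, dtype=float))
    return BootstrapBundle(B=pred_lab.shape[0], models=[None] * pred_lab.shape[0],
                           resamples=[np.array([])] * pred_lab.shape[0],
                           holdouts=[np.asarray(h) for h in holdouts],
                           pred_lab=pred_lab, pred_unl=pred_unl,
                           avg_pred_unl=pred_unl.mean(axis=0))


class TestFitBootstrapModels:
    def test_resample_size_and_determinism(self, rng):
        X = rng.normal(size=(100, 2))
        y = rng.normal(size=100)
        Xu = rng.normal(size=(20, 2))
        b1 = fit_bootstrap_models(X, y, Xu, K=10, B=5, learner=LinearLearner(),
                                  seed=7)
        b2 = fit_bootstrap_models(X, y, Xu, K=10, B=5, learner=LinearLearner(),
                                  seed=7)
        for r in b1.resamples:
            assert len(r) == 90
        for r1, r2, h1, h2 in zip(b1.resamples, b2.resamples,
                                  b1.holdouts, b2.holdouts):
            np.testing.assert_array_equal(r1, r2)
            np.testing.assert_array_equal(h1, h2)
        # holdout means never-drawn
        for r, h in zip(b1.resamples, b1.holdouts):
            assert set(r).isdisjoint(set(h))
            assert set(r) | set(h) == set(range(100))

    def test_constant_learner_average(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        Xu = rng.normal(size=(10, 2))
        boot = fit_bootstrap_models(X, y, Xu, K=3, B=4,
                                    learner=ConstantLearner(5.0), seed=0)
        np.testing.assert_allclose(boot.avg_pred_unl, 5.0)

    def test_subsample_mode_holdout_is_complement(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        boot = fit_bootstrap_models(X, y, np.zeros((5, 2)), K=5, B=3,
                                    learner=ConstantLearner(0.0), seed=1,
                                    boot_mode="subsample")
        for r, h in zip(boot.resamples, boot.holdouts):
            assert len(np.unique(r)) == 40
            assert len(h) == 10


class TestSigmaTheta:
    def test_mean_estimand_reduces_to_prediction_variance(self, rng):
        """Gradient 2(theta - f) makes Sigma_theta = 4 Var(fbar)."""
        pred_unl = rng.normal(size=(3, 50))
        boot = _toy_boot(np.zeros((3, 4)), pred_unl, [np.arange(4)] * 3)
        st = estimate_sigma_theta(boot, None, make_estimand("mean"),
                                  np.array([0.0]))
        assert st[0, 0] == pytest.approx(4.0 * boot.avg_pred_unl.var(ddof=1))

    def test_two_row_hand_case(self):
        boot = _toy_boot(np.zeros((2, 2)), np.array([[0.0, 2.0], [0.0, 2.0]]),
                         [np.arange(2)] * 2)
        st = estimate_sigma_theta(boot, None, make_estimand("mean"),
                                  np.array([0.0]))
        # fbar values (0, 2): Var = 2 (ddof=1); gradient doubles -> x4
        assert st[0, 0] == pytest.approx(4.0 * 2.0)

    def test_constant_predictions_zero_matrix(self):
        boot = _toy_boot(np.zeros((2, 3)), np.full((2, 10), 1.7),
                         [np.arange(3)] * 2)
        st = estimate_sigma_theta(boot, None, make_estimand("mean"),
                                  np.array([0.0]))
        assert st[0, 0] == pytest.approx(0.0, abs=1e-15)


class TestSigmaDelta:
    def test_perfect_models_zero_matrix(self, rng):
        y = rng.normal(size=6)
        boot = _toy_boot(np.vstack([y, y]), np.zeros((2, 4)),
                         [np.arange(3), np.arange(3, 6)])
        sd = estimate_sigma_delta(boot, None, y, make_estimand("mean"),
                                  np.array([0.0]))
        assert sd[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_constant_model_hand_case(self):
        """c=2 on Y=(1,2,3,4): differences 2(y - 2) -> 4 Var(y - 2)."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        boot = _toy_boot(np.full((1, 4), 2.0), np.zeros((1, 2)), [np.arange(4)])
        sd = estimate_sigma_delta(boot, None, y, make_estimand("mean"),
                                  np.array([0.0]))
        assert sd[0, 0] == pytest.approx(4.0 * np.var(2.0 - y, ddof=1))

    def test_models_not_averaged(self):
        """Pooled per-model differences, not differences of the average."""
        y = np.zeros(2)
        pred_lab = np.array([[1.0, 1.0], [-1.0, -1.0]])
        boot = _toy_boot(pred_lab, np.zeros((2, 2)),
                         [np.arange(2), np.arange(2)])
        sd = estimate_sigma_delta(boot, None, y, make_estimand("mean"),
                                  np.array([0.0]))
        # pooled diffs 2*(1,1,-1,-1): variance 16/3; averaging models would give 0
        assert sd[0, 0] == pytest.approx(np.var([2, 2, -2, -2], ddof=1))


class TestHessian:
    def test_ols_pooled_second_moment(self, rng):
        X = rng.normal(size=(10, 2))
        Xu = rng.normal(size=(20, 2))
        H = estimate_hessian(X, Xu, make_estimand("ols", d=2), np.zeros(2))
        pooled = np.vstack([X, Xu])
        np.testing.assert_allclose(H, pooled.T @ pooled / 30, atol=1e-12)

    def test_glm_logistic_at_zero_quarter_scaling(self, rng):
        X = rng.normal(size=(15, 2))
        Xu = rng.normal(size=(5, 2))
        H = estimate_hessian(X, Xu, make_estimand("glm", d=2, link="logistic"),
                             np.zeros(2))
        pooled = np.vstack([X, Xu])
        np.testing.assert_allclose(H, 0.25 * pooled.T @ pooled / 20, atol=1e-12)


class TestAssembleSandwich:
    def test_hand_arithmetic(self):
        cov = assemble_sandwich(np.array([[1.0]]), np.array([[4.0]]),
                                np.array([[1.0]]), n=100, N=10_000)
        assert cov.v_hat[0, 0] == pytest.approx(4.01)
        assert cov.sandwich[0, 0] == pytest.approx(4.01)

    def test_large_N_limit(self):
        cov = assemble_sandwich(np.array([[1.0]]), np.array([[4.0]]),
                                np.array([[1.0]]), n=100, N=10 ** 12)
        assert cov.v_hat[0, 0] == pytest.approx(4.0, abs=1e-9)

    def test_identity_hessian_passthrough_and_symmetry(self, rng):
        A = rng.normal(size=(3, 3))
        st = A @ A.T
        sd = np.eye(3)
        cov = assemble_sandwich(st, sd, np.eye(3), n=10, N=20)
        np.testing.assert_allclose(cov.sandwich, cov.v_hat, atol=1e-12)
        np.testing.assert_allclose(cov.sandwich, cov.sandwich.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov.sandwich).min() >= -1e-12

    def test_singular_hessian_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            assemble_sandwich(np.eye(2), np.eye(2), np.zeros((2, 2)), 10, 20)


class TestStabilization:
    def test_sigma_theta_stabilizes_in_B(self):
        """Deterministic learner, fixed data: doubling B barely moves Sigma_theta."""
        data = generate_mean_dgp(DGPConfig(n=80, N=500, r=0.5, seed=3))
        est = make_estimand("mean")
        vals = []
        for B in (20, 40):
            boot = fit_bootstrap_models(data.X, data.y, data.X_unlabeled,
                                        K=8, B=B, learner=LinearLearner(), seed=5)
            vals.append(estimate_sigma_theta(boot, None, est,
                                             np.array([4.0]))[0, 0])
        assert vals[1] == pytest.approx(vals[0], rel=0.2)
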