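"""Point estimators and the scikit-learn-style estimator classes.

The workhorse is the cross-prediction estimator: impute labels for the
unlabeled rows with K fold-excluded models, then subtract an out-of-fold
estimate of the imputation bias computed on the labeled rows.  For the mean
the estimator is

    theta+ = mean_j,i f_j(Xu_i) / K  -  mean_i (f_oof(X_i) - Y_i),

and in general theta+ minimizes the debiased empirical loss L+.  Baselines:
the classical M-estimator (labeled data only), prediction-powered inference
with a single split-trained model, and two heuristics — dropping the
debiasing term, and training one model on all labeled data without folds.

Module-level functions compute point estimates from a fitted
:class:`~crosspred.crossfit.CrossFitBundle`; the estimator classes
(:class:`CrossPrediction`, :class:`ClassicalInference`, :class:`PPI`,
:class:`NoDebias`, :class:`NoFolds`) wrap them together with the bootstrap
variance machinery and expose fitted attributes ``theta_``, ``se_``,
``ci_lower_``, ``ci_upper_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .crossfit import CrossFitBundle, FoldAssignment, assign_folds, fit_crossfit
from .estimands import (Estimand, UnsupportedOperationError, gradient,
                        hessian_contrib, make_estimand, _psi_prime,
                        _psi_double_prime)
from .intervals import (ConfidenceInterval, bonferroni_cis,
                        invert_gradient_test, quantile_ci, wald_ci)
from .learners import BoostedTreeLearner
from .variance import (BootstrapBundle, CovarianceEstimate, assemble_sandwich,
                       estimate_hessian, estimate_sigma_delta,
                       estimate_sigma_theta, fit_bootstrap_models, _cov)


# ---------------------------------------------------------------------------
# containers

@dataclass
class CdfPair:
    """Corrected empirical CDF used by quantile estimation.

    ``F_plus`` is the K-model average empirical CDF of the predictions on
    the unlabeled data; ``Delta_plus`` is the difference between the
    empirical CDFs of the out-of-fold predictions and of the true outcomes
    on the labeled data.  Both are step functions, tabulated on ``grid``
    (the sorted union of their jump points).
    """

    grid: np.ndarray
    F_plus: np.ndarray
    Delta_plus: np.ndarray

    @property
    def corrected(self) -> np.ndarray:
        return self.F_plus - self.Delta_plus


@dataclass
class PointEstimate:
    theta: np.ndarray
    method: str
    estimand: Estimand
    diagnostics: dict = field(default_factory=dict)
    cdf: CdfPair | None = None

    def __post_init__(self) -> None:
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))


# ---------------------------------------------------------------------------
# cross-prediction point estimators

def crosspred_mean(bundle: CrossFitBundle, y: np.ndarray) -> PointEstimate:
    """Debiased mean: average imputation minus average out-of-fold error."""
    if bundle.unl_pred_avg.size == 0:
        raise ValueError("unlabeled set is empty")
    y = np.asarray(y, dtype=float)
    theta = bundle.unl_pred_avg.mean() - (bundle.oof_pred - y).mean()
    return PointEstimate(theta, "crosspred", make_estimand("mean"))


def _ecdf_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    s = np.sort(np.asarray(values, dtype=float).ravel())
    return np.searchsorted(s, grid, side="right") / s.size


def crosspred_quantile(bundle: CrossFitBundle, y: np.ndarray,
                       q: float) -> PointEstimate:
    """Debiased quantile via the corrected-CDF identity.

    The corrected CDF ``F+ - Delta+`` changes value only at labeled outcomes
    and unlabeled predictions, so the smallest grid value at which it
    reaches ``q`` is the exact minimizer of the debiased pinball loss.
    """
    y = np.asarray(y, dtype=float)
    preds = bundle.unl_pred.ravel()
    if preds.size == 0 and y.size == 0:
        raise ValueError("empty grid: no outcomes or predictions")
    grid = np.unique(np.concatenate([y, preds]))
    F = _ecdf_on_grid(preds, grid)
    Delta = _ecdf_on_grid(bundle.oof_pred, grid) - _ecdf_on_grid(y, grid)
    cdf = CdfPair(grid=grid, F_plus=F, Delta_plus=Delta)
    reach = np.flatnonzero(cdf.corrected >= q)
    if reach.size == 0:  # cannot happen: corrected CDF is 1 at the grid max
        raise RuntimeError("corrected CDF never reaches q")
    theta = grid[reach[0]]
    est = make_estimand("quantile", q=q)
    return PointEstimate(theta, "crosspred", est, cdf=cdf)


def _solve_gram(gram: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"design Gram matrix numerically singular (cond={cond:.3e})")
    return np.linalg.solve(gram, rhs)


def crosspred_ols(bundle: CrossFitBundle, X_design: np.ndarray, y: np.ndarray,
                  X_unl_design: np.ndarray) -> PointEstimate:
    """Closed-form debiased least squares.

    ``theta+ = (Xu'Xu)^-1 (Xu' f_avg(Xu) - (N/n) X'(f_oof(X) - Y))`` — the
    usual normal equations with imputed responses, plus a debiasing term
    scaled up by N/n because the unlabeled Gram matrix averages over N rows.
    """
    Xd = np.asarray(X_design, dtype=float)
    Xud = np.asarray(X_unl_design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, N = len(y), Xud.shape[0]
    rhs = Xud.T @ bundle.unl_pred_avg - (N / n) * (Xd.T @ (bundle.oof_pred - y))
    theta = _solve_gram(Xud.T @ Xud, rhs)
    est = make_estimand("ols", d=Xd.shape[1])
    grad = grad_Lplus(bundle, Xd, y, Xud, est, theta)
    return PointEstimate(theta, "crosspred", est,
                         diagnostics={"grad_norm": float(np.linalg.norm(grad))})


def grad_Lplus(bundle: CrossFitBundle, X_design: np.ndarray | None,
               y: np.ndarray, X_unl_design: np.ndarray | None,
               estimand: Estimand, theta: np.ndarray) -> np.ndarray:
    """Gradient of the debiased loss L+ at ``theta``.

    For GLM families the ``psi'`` terms of the two labeled sums cancel
    exactly, leaving the unlabeled imputed score plus the out-of-fold
    gradient-bias correction.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    y = np.asarray(y, dtype=float)
    if estimand.kind == "mean":
        g = 2.0 * (theta[0] - bundle.unl_pred_avg.mean()) \
            + 2.0 * (bundle.oof_pred - y).mean()
        return np.array([g])
    if estimand.kind == "quantile":
        q = estimand.q
        F = (bundle.unl_pred.ravel() <= theta[0]).mean()
        Delta = (bundle.oof_pred <= theta[0]).mean() - (y <= theta[0]).mean()
        return np.array([F - Delta - q])
    link = "identity" if estimand.kind == "ols" else estimand.link
    s = X_unl_design @ theta
    g_unl = X_unl_design.T @ (_psi_prime(link, s) - bundle.unl_pred_avg) / X_unl_design.shape[0]
    g_bias = X_design.T @ (bundle.oof_pred - y) / len(y)
    return g_unl + g_bias


def _damped_newton(grad_fn, hess_fn, theta0: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, dict]:
    """Newton iteration with step halving on the gradient norm."""
    theta = np.atleast_1d(np.asarray(theta0, dtype=float)).copy()
    trace = []
    for it in range(max_iter):
        g = grad_fn(theta)
        gn = float(np.linalg.norm(g))
        trace.append(gn)
        if gn <= tol:
            return theta, {"iterations": it, "grad_norm": gn}
        step = np.linalg.solve(hess_fn(theta), g)
        t = 1.0
        for _ in range(60):
            cand = theta - t * step
            if np.linalg.norm(grad_fn(cand)) < gn:
                break
            t *= 0.5
        theta = theta - t * step
    raise RuntimeError(f"Newton did not converge in {max_iter} iterations; "
                       f"gradient-norm trace tail: {trace[-5:]}")


def crosspred_glm(bundle: CrossFitBundle, X_design: np.ndarray, y: np.ndarray,
                  X_unl_design: np.ndarray, estimand: Estimand,
                  theta0: np.ndarray | None = None) -> PointEstimate:
    """Debiased GLM coefficients: damped-Newton root of the L+ score.

    The Hessian of L+ is the unlabeled-average ``psi''(x'theta) x x'``,
    positive semidefinite, so L+ is convex for GLM families.  Initialized at
    the classical GLM fit on the labeled data.
    """
    Xd = np.asarray(X_design, dtype=float)
    Xud = np.asarray(X_unl_design, dtype=float)
    y = np.asarray(y, dtype=float)
    link = estimand.link or "identity"
    if theta0 is None:
        theta0 = classical_estimate(Xd, y, estimand).theta

    def grad_fn(t):
        return grad_Lplus(bundle, Xd, y, Xud, estimand, t)

    def hess_fn(t):
        w = _psi_double_prime(link, Xud @ t)
        H = (Xud * w[:, None]).T @ Xud / Xud.shape[0]
        # ridge-free safeguard: fall back to the OLS Gram when curvature dies
        if np.linalg.cond(H) > 1e12:
            H = Xud.T @ Xud / Xud.shape[0]
        return H

    theta, diag = _damped_newton(grad_fn, hess_fn, theta0)
    return PointEstimate(theta, "crosspred", estimand, diagnostics=diag)


# ---------------------------------------------------------------------------
# baselines

def classical_estimate(X_design: np.ndarray | None, y: np.ndarray,
                       estimand: Estimand) -> PointEstimate:
    """The labeled-data-only M-estimator."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if estimand.kind == "mean":
        return PointEstimate(y.mean(), "classical", estimand)
    if estimand.kind == "quantile":
        s = np.sort(y)
        k = int(np.ceil(estimand.q * n)) - 1  # smallest order stat with ECDF >= q
        return PointEstimate(s[max(k, 0)], "classical", estimand)
    Xd = np.asarray(X_design, dtype=float)
    if n < Xd.shape[1] + 1:
        raise ValueError("need n >= d + 1 labeled rows")
    if estimand.kind == "ols":
        theta = _solve_gram(Xd.T @ Xd, Xd.T @ y)
        return PointEstimate(theta, "classical", estimand)

    link = estimand.link

    def grad_fn(t):
        return Xd.T @ (_psi_prime(link, Xd @ t) - y) / n

    def hess_fn(t):
        w = _psi_double_prime(link, Xd @ t)
        H = (Xd * w[:, None]).T @ Xd / n
        if np.linalg.cond(H) > 1e12:
            H = Xd.T @ Xd / n
        return H

    theta, diag = _damped_newton(grad_fn, hess_fn, np.zeros(Xd.shape[1]))
    return PointEstimate(theta, "classical", estimand, diagnostics=diag)


def _single_model_bundle(model, X: np.ndarray, rows: np.ndarray,
                         X_unlabeled: np.ndarray, seed: int) -> CrossFitBundle:
    """Wrap one fitted model as a K=1 bundle over the given labeled rows."""
    pred_rows = np.asarray(model.predict(X[rows]), dtype=float)
    pred_unl = np.asarray(model.predict(X_unlabeled), dtype=float)[None, :]
    folds = FoldAssignment(n=len(rows), K=1,
                           fold_of=np.zeros(len(rows), dtype=np.int64), seed=seed)
    return CrossFitBundle(models=[model], folds=folds, oof_pred=pred_rows,
                          unl_pred=pred_unl, unl_pred_avg=pred_unl[0])


def ppi_split(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded shuffle, then the first ``round(train_fraction * n)`` rows train."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_tr = int(round(train_fraction * n))
    if n_tr < 2 or n - n_tr < 2:
        raise ValueError(f"degenerate split: n_tr={n_tr}, n_held={n - n_tr}")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_tr], perm[n_tr:]


def ppi_estimate(X: np.ndarray, y: np.ndarray, X_unlabeled: np.ndarray,
                 estimand: Estimand, train_fraction: float, learner,
                 seed: int, design_cols=None) -> tuple[PointEstimate, CrossFitBundle, np.ndarray]:
    """Prediction-powered estimate with a split-trained model.

    Returns the point estimate together with the single-model bundle over
    the held-out rows and the held-out index set (the ingredients of the
    conditional-on-the-model variance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xu = np.asarray(X_unlabeled, dtype=float)
    train, held = ppi_split(len(y), train_fraction, seed)
    model = learner.fit(X[train], y[train], seed=seed)
    bundle = _single_model_bundle(model, X, held, Xu, seed)
    y_held = y[held]
    Xd = _design(X, design_cols)
    Xud = _design(Xu, design_cols)
    if estimand.kind == "mean":
        est = crosspred_mean(bundle, y_held)
    elif estimand.kind == "quantile":
        est = crosspred_quantile(bundle, y_held, estimand.q)
    elif estimand.kind == "ols":
        est = crosspred_ols(bundle, Xd[held], y_held, Xud)
    else:
        est = crosspred_glm(bundle, Xd[held], y_held, Xud, estimand)
    est.method = "ppi"
    est.estimand = estimand
    return est, bundle, held


def heuristic_no_debias(bundle: CrossFitBundle, estimand: Estimand,
                        X_unl_design: np.ndarray | None = None) -> PointEstimate:
    """Average the imputations, skip the bias correction (invalid in general)."""
    if estimand.kind == "mean":
        return PointEstimate(bundle.unl_pred_avg.mean(), "no_debias", estimand)
    if estimand.kind == "ols":
        Xud = np.asarray(X_unl_design, dtype=float)
        theta = _solve_gram(Xud.T @ Xud, Xud.T @ bundle.unl_pred_avg)
        return PointEstimate(theta, "no_debias", estimand)
    raise UnsupportedOperationError("no-debias heuristic supports mean and ols only")


def heuristic_no_folds(X: np.ndarray, y: np.ndarray, X_unlabeled: np.ndarray,
                       estimand: Estimand, learner, seed: int,
                       design_cols=None) -> tuple[PointEstimate, CrossFitBundle]:
    """Debiased plug-in with one model trained on all labeled rows (no folds)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xu = np.asarray(X_unlabeled, dtype=float)
    model = learner.fit(X, y, seed=seed)
    bundle = _single_model_bundle(model, X, np.arange(len(y)), Xu, seed)
    if estimand.kind == "mean":
        est = crosspred_mean(bundle, y)
    elif estimand.kind == "ols":
        Xd = _design(X, design_cols)
        Xud = _design(Xu, design_cols)
        est = crosspred_ols(bundle, Xd, y, Xud)
    else:
        raise UnsupportedOperationError("no-folds heuristic supports mean and ols only")
    est.method = "no_folds"
    est.estimand = estimand
    return est, bundle


# ---------------------------------------------------------------------------
# scikit-learn-style estimator classes

def _design(X: np.ndarray, design_cols) -> np.ndarray:
    return X if design_cols is None else X[:, list(design_cols)]


def _as_seed(random_state) -> int:
    if random_state is None:
        return int(np.random.SeedSequence().entropy % (2 ** 31))
    return int(random_state) % (2 ** 31)


def _validate(X, y=None, name="X"):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"{name} must be a nonempty 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return X, y


class _BaseSemiSupervised(BaseEstimator):
    """Shared plumbing: estimand resolution, design slicing, CI reporting."""

    def _resolve_estimand(self, X: np.ndarray) -> Estimand:
        if isinstance(self.estimand, Estimand):
            return self.estimand
        kind = self.estimand
        if kind in ("mean", "quantile"):
            return make_estimand(kind, q=self.q if kind == "quantile" else None)
        d = X.shape[1] if self.design_cols is None else len(self.design_cols)
        return make_estimand(kind, d=d,
                             link=self.link if kind == "glm" else None)

    def _store_cis(self, cis: list[ConfidenceInterval]) -> None:
        self.cis_ = cis
        self.ci_lower_ = np.array([ci.lower for ci in cis])
        self.ci_upper_ = np.array([ci.upper for ci in cis])

    @property
    def interval_(self) -> tuple[float, float]:
        """(lower, upper) for the first reporting coordinate."""
        return float(self.ci_lower_[0]), float(self.ci_upper_[0])

    def _wald_like_cis(self, theta: np.ndarray, cov: CovarianceEstimate,
                       n_eff: int, est: Estimand) -> list[ConfidenceInterval]:
        method = getattr(self, "ci_method", "wald")
        if method == "bonferroni":
            all_cis = bonferroni_cis(theta, cov, n_eff, self.alpha)
            return [all_cis[i] for i in est.coords]
        return [wald_ci(theta, cov, n_eff, self.alpha, i) for i in est.coords]


class CrossPrediction(_BaseSemiSupervised):
    """Cross-prediction-powered inference for an M-estimand.

    Fits K fold-excluded models on the labeled data, imputes labels on the
    unlabeled data, debiases with the out-of-fold residuals, and estimates
    the asymptotic variance with B bootstrap model refits.

    Parameters
    ----------
    estimand : {"mean", "quantile", "ols", "glm"} or Estimand
    q : float
        Quantile level (quantile estimand only).
    link : {"identity", "logistic"}
        GLM link (glm estimand only).
    design_cols : sequence of int or None
        Columns of X forming the regression design for ols/glm targets.
        The learner always sees *all* columns; excluded-but-predictive
        features thereby still sharpen the inference.
    K : int
        Number of cross-fitting folds.
    B : int
        Number of bootstrap model refits for variance estimation.
    learner : object, optional
        ``fit(X, y, seed) -> model`` factory; defaults to
        :class:`~crosspred.learners.BoostedTreeLearner`.
    alpha : float
        Miscoverage level; intervals have nominal level ``1 - alpha``.
    ci_method : {"wald", "bonferroni", "invert"}
    boot_mode : {"replacement", "subsample"}
    random_state : int, optional

    Attributes
    ----------
    theta_ : ndarray of shape (d,)
    se_ : ndarray — per reporting coordinate (NaN for quantile targets)
    ci_lower_, ci_upper_ : ndarray — per reporting coordinate
    covariance_ : CovarianceEstimate or None
    confidence_set_ : ConfidenceSet or None (quantile / inversion paths)
    """

    def __init__(self, estimand="mean", *, q=0.75, link="logistic",
                 design_cols=None, K=10, B=30, learner=None, alpha=0.1,
                 ci_method="wald", boot_mode="replacement", random_state=None):
        self.estimand = estimand
        self.q = q
        self.link = link
        self.design_cols = design_cols
        self.K = K
        self.B = B
        self.learner = learner
        self.alpha = alpha
        self.ci_method = ci_method
        self.boot_mode = boot_mode
        self.random_state = random_state

    def fit(self, X, y, X_unlabeled=None):
        if X_unlabeled is None:
            raise ValueError("CrossPrediction requires X_unlabeled")
        X, y = _validate(X, y)
        Xu = _validate(X_unlabeled, name="X_unlabeled")
        seed = _as_seed(self.random_state)
        learner = self.learner if self.learner is not None else BoostedTreeLearner()
        folds = assign_folds(len(y), self.K, seed)
        bundle = fit_crossfit(X, y, Xu, folds, learner)
        boot = fit_bootstrap_models(X, y, Xu, self.K, self.B, learner,
                                    seed + 100_000, self.boot_mode)
        return self._fit_from_bundles(X, y, Xu, bundle, boot)

    def _fit_from_bundles(self, X, y, Xu, bundle: CrossFitBundle,
                          boot: BootstrapBundle):
        """Inference given already-trained cross-fit and bootstrap models.

        Lets several estimands of the same data share one set of model fits
        (the models do not depend on the estimand).
        """
        est = self._resolve_estimand(X)
        n, N = len(y), Xu.shape[0]
        Xd = _design(X, self.design_cols) if est.uses_features else None
        Xud = _design(Xu, self.design_cols) if est.uses_features else None

        if est.kind == "mean":
            point = crosspred_mean(bundle, y)
        elif est.kind == "quantile":
            point = crosspred_quantile(bundle, y, est.q)
        elif est.kind == "ols":
            point = crosspred_ols(bundle, Xd, y, Xud)
        else:
            point = crosspred_glm(bundle, Xd, y, Xud, est)

        self.estimand_ = est
        self.theta_ = point.theta
        self.point_estimate_ = point
        self.bundle_ = bundle
        self.boot_ = boot
        self.n_, self.N_ = n, N
        self.confidence_set_ = None

        if est.kind == "quantile":
            self._fit_quantile_ci(point, boot, y, n, N)
        else:
            theta = point.theta
            st = estimate_sigma_theta(boot, Xud, est, theta)
            sd = estimate_sigma_delta(boot, Xd, y, est, theta)
            H = estimate_hessian(Xd, Xud, est, theta)
            cov = assemble_sandwich(st, sd, H, n, N)
            self.covariance_ = cov
            self.se_ = np.array([np.sqrt(cov.sandwich[i, i] / n) for i in est.coords])
            if self.ci_method == "invert":
                self._fit_inversion_ci(point, bundle, boot, Xd, y, Xud, est, cov)
            else:
                self._store_cis(self._wald_like_cis(theta, cov, n, est))
        return self

    # -- quantile: exact CDF-inversion confidence set -----------------------
    def _fit_quantile_ci(self, point, boot: BootstrapBundle, y, n, N) -> None:
        sorted_fbar = np.sort(boot.avg_pred_unl)
        pooled_pred = np.concatenate([boot.pred_lab[b, h]
                                      for b, h in enumerate(boot.holdouts)])
        pooled_y = np.concatenate([y[h] for h in boot.holdouts])
        st_eval = _indicator_var_eval(sorted_fbar)
        sd_eval = _indicator_diff_var_eval(pooled_pred, pooled_y)
        cs = quantile_ci(point.cdf, st_eval, sd_eval, n, N, point.estimand.q,
                         self.alpha)
        self.covariance_ = None
        self.se_ = np.array([np.nan])
        self.confidence_set_ = cs
        if cs.empty:
            raise RuntimeError("quantile confidence set is empty; "
                               "check the model/grid configuration")
        self._store_cis([cs.hull])

    # -- mean/glm: score-test inversion over a Wald-centered grid -----------
    def _fit_inversion_ci(self, point, bundle, boot, Xd, y, Xud, est, cov) -> None:
        theta = point.theta
        if est.d > 1:
            # exact ellipsoidal set; report its per-coordinate projections
            from scipy import stats as _st
            r = np.sqrt(_st.chi2.ppf(1 - self.alpha, df=est.d) / self.n_)
            cis = [ConfidenceInterval(theta[i] - r * np.sqrt(cov.sandwich[i, i]),
                                      theta[i] + r * np.sqrt(cov.sandwich[i, i]),
                                      1 - self.alpha, i, method="ellipsoid")
                   for i in est.coords]
            self._store_cis(cis)
            return
        se = np.sqrt(cov.sandwich[0, 0] / self.n_)
        grid = np.linspace(theta[0] - 6 * se, theta[0] + 6 * se, 400)

        def grad_fn(t):
            return grad_Lplus(bundle, Xd, y, Xud, est, t)

        def vtheta_fn(t):
            st = estimate_sigma_theta(boot, Xud, est, t)
            sd = estimate_sigma_delta(boot, Xd, y, est, t)
            return (self.n_ / self.N_) * st + sd

        cs = invert_gradient_test(grid, grad_fn, vtheta_fn, self.n_, 1, self.alpha)
        self.confidence_set_ = cs
        if cs.empty:
            raise RuntimeError("inversion confidence set is empty")
        self._store_cis([cs.hull])


def _indicator_var_eval(sorted_values: np.ndarray):
    """Vectorized unbiased variance of 1{V <= theta} over tabulated values."""
    m = sorted_values.size

    def eval_(grid: np.ndarray) -> np.ndarray:
        p = np.searchsorted(sorted_values, grid, side="right") / m
        return p * (1.0 - p) * m / max(m - 1, 1)

    return eval_


def _indicator_diff_var_eval(a: np.ndarray, c: np.ndarray):
    """Unbiased variance of 1{A <= theta} - 1{C <= theta} over paired values.

    Uses the identity sum v^2 = #{A<=t} + #{C<=t} - 2 #{max(A,C)<=t} so the
    whole grid is handled with three searchsorted calls.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    M = a.size
    sa, sc = np.sort(a), np.sort(c)
    sm = np.sort(np.maximum(a, c))

    def eval_(grid: np.ndarray) -> np.ndarray:
        ca = np.searchsorted(sa, grid, side="right")
        cc = np.searchsorted(sc, grid, side="right")
        cb = np.searchsorted(sm, grid, side="right")
        s1 = ca - cc
        s2 = ca + cc - 2 * cb
        return (s2 - s1 ** 2 / M) / max(M - 1, 1)

    return eval_


class ClassicalInference(_BaseSemiSupervised):
    """Labeled-data-only M-estimation with robust (sandwich) CLT intervals.

    Ignores ``X_unlabeled``.  The quantile target uses exact CDF-test
    inversion on the order statistics rather than a Wald interval.
    """

    def __init__(self, estimand="mean", *, q=0.75, link="logistic",
                 design_cols=None, alpha=0.1, ci_method="wald",
                 random_state=None):
        self.estimand = estimand
        self.q = q
        self.link = link
        self.design_cols = design_cols
        self.alpha = alpha
        self.ci_method = ci_method
        self.random_state = random_state

    def fit(self, X, y, X_unlabeled=None):
        X, y = _validate(X, y)
        est = self._resolve_estimand(X)
        Xd = _design(X, self.design_cols) if est.uses_features else None
        n = len(y)
        point = classical_estimate(Xd, y, est)
        self.estimand_ = est
        self.theta_ = point.theta
        self.point_estimate_ = point
        self.n_, self.N_ = n, 0
        self.confidence_set_ = None

        if est.kind == "quantile":
            grid = np.unique(y)
            cdf = CdfPair(grid=grid, F_plus=_ecdf_on_grid(y, grid),
                          Delta_plus=np.zeros_like(grid))
            sd_eval = _indicator_var_eval(np.sort(y))
            cs = quantile_ci(cdf, lambda g: np.zeros_like(g), sd_eval,
                             n, max(n, 2), est.q, self.alpha)
            self.covariance_ = None
            self.se_ = np.array([np.nan])
            self.confidence_set_ = cs
            if cs.empty:
                raise RuntimeError("classical quantile confidence set is empty")
            self._store_cis([cs.hull])
            return self

        G = gradient(est, point.theta, Xd, y)
        V = _cov(G)
        H = hessian_contrib(est, point.theta, Xd) if est.kind != "mean" \
            else hessian_contrib(est, point.theta, None)
        cov = assemble_sandwich(np.zeros_like(V), V, H, n, max(n, 2))
        self.covariance_ = cov
        self.se_ = np.array([np.sqrt(cov.sandwich[i, i] / n) for i in est.coords])
        self._store_cis(self._wald_like_cis(point.theta, cov, n, est))
        return self


class _SingleModelInference(_BaseSemiSupervised):
    """Shared CI assembly for the single-model methods (PPI, no-folds)."""

    def _sandwich_ci(self, bundle: CrossFitBundle, Xd_rows, y_rows, Xud,
                     est: Estimand, theta: np.ndarray, n_eff: int, N: int):
        boot = BootstrapBundle(
            B=1, models=bundle.models, resamples=[np.array([], dtype=int)],
            holdouts=[np.arange(len(y_rows))],
            pred_lab=bundle.oof_pred[None, :], pred_unl=bundle.unl_pred,
            avg_pred_unl=bundle.unl_pred_avg)
        st = estimate_sigma_theta(boot, Xud, est, theta)
        sd = estimate_sigma_delta(boot, Xd_rows, y_rows, est, theta)
        H = estimate_hessian(Xd_rows, Xud, est, theta)
        cov = assemble_sandwich(st, sd, H, n_eff, N)
        self.covariance_ = cov
        self.se_ = np.array([np.sqrt(cov.sandwich[i, i] / n_eff) for i in est.coords])
        self._store_cis(self._wald_like_cis(theta, cov, n_eff, est))

    def _quantile_ci(self, bundle: CrossFitBundle, point, y_rows, n_eff, N):
        st_eval = _indicator_var_eval(np.sort(bundle.unl_pred_avg))
        sd_eval = _indicator_diff_var_eval(bundle.oof_pred, y_rows)
        cs = quantile_ci(point.cdf, st_eval, sd_eval, n_eff, N,
                         point.estimand.q, self.alpha)
        self.covariance_ = None
        self.se_ = np.array([np.nan])
        self.confidence_set_ = cs
        if cs.empty:
            raise RuntimeError("quantile confidence set is empty")
        self._store_cis([cs.hull])


class PPI(_SingleModelInference):
    """Prediction-powered inference with data splitting.

    A single model is trained on a seeded random ``train_fraction`` of the
    labeled rows; the held-out rows debias its imputations on the unlabeled
    data.  Inference is conditional on the trained model, so no bootstrap is
    needed.
    """

    def __init__(self, estimand="mean", *, q=0.75, link="logistic",
                 design_cols=None, train_fraction=0.5, learner=None,
                 alpha=0.1, ci_method="wald", random_state=None):
        self.estimand = estimand
        self.q = q
        self.link = link
        self.design_cols = design_cols
        self.train_fraction = train_fraction
        self.learner = learner
        self.alpha = alpha
        self.ci_method = ci_method
        self.random_state = random_state

    def fit(self, X, y, X_unlabeled=None):
        if X_unlabeled is None:
            raise ValueError("PPI requires X_unlabeled")
        X, y = _validate(X, y)
        Xu = _validate(X_unlabeled, name="X_unlabeled")
        est = self._resolve_estimand(X)
        seed = _as_seed(self.random_state)
        learner = self.learner if self.learner is not None else BoostedTreeLearner()
        point, bundle, held = ppi_estimate(X, y, Xu, est, self.train_fraction,
                                           learner, seed, self.design_cols)
        n_eff, N = len(held), Xu.shape[0]
        self.estimand_ = est
        self.theta_ = point.theta
        self.point_estimate_ = point
        self.n_, self.N_ = n_eff, N
        self.held_idx_ = held
        self.confidence_set_ = None
        Xd_held = _design(X, self.design_cols)[held] if est.uses_features else None
        Xud = _design(Xu, self.design_cols) if est.uses_features else None
        if est.kind == "quantile":
            self._quantile_ci(bundle, point, y[held], n_eff, N)
        else:
            self._sandwich_ci(bundle, Xd_held, y[held], Xud, est,
                              point.theta, n_eff, N)
        return self


class NoFolds(_SingleModelInference):
    """Heuristic: one model trained on all labeled rows, then debiased.

    The CI treats the model as if it were independent of the labeled data
    (it is not), applying the CLT to the two averages separately — the
    moderate, vanishing-with-n failure mode.
    """

    def __init__(self, estimand="mean", *, design_cols=None, learner=None,
                 alpha=0.1, ci_method="wald", random_state=None):
        self.estimand = estimand
        self.design_cols = design_cols
        self.learner = learner
        self.alpha = alpha
        self.ci_method = ci_method
        self.random_state = random_state
        self.q = None
        self.link = None

    def fit(self, X, y, X_unlabeled=None):
        if X_unlabeled is None:
            raise ValueError("NoFolds requires X_unlabeled")
        X, y = _validate(X, y)
        Xu = _validate(X_unlabeled, name="X_unlabeled")
        est = self._resolve_estimand(X)
        seed = _as_seed(self.random_state)
        learner = self.learner if self.learner is not None else BoostedTreeLearner()
        point, bundle = heuristic_no_folds(X, y, Xu, est, learner, seed,
                                           self.design_cols)
        n, N = len(y), Xu.shape[0]
        self.estimand_ = est
        self.theta_ = point.theta
        self.point_estimate_ = point
        self.n_, self.N_ = n, N
        self.confidence_set_ = None
        Xd = _design(X, self.design_cols) if est.uses_features else None
        Xud = _design(Xu, self.design_cols) if est.uses_features else None
        self._sandwich_ci(bundle, Xd, y, Xud, est, point.theta, n, N)
        return self


class NoDebias(_BaseSemiSupervised):
    """Heuristic: average the K-fold imputations, skip the debiasing.

    The CI applies the CLT to the imputed values conditional on the trained
    models, so it reflects only imputation noise and inherits any prediction
    bias — the detrimental-to-coverage failure mode.
    """

    def __init__(self, estimand="mean", *, design_cols=None, K=10,
                 learner=None, alpha=0.1, ci_method="wald", random_state=None):
        self.estimand = estimand
        self.design_cols = design_cols
        self.K = K
        self.learner = learner
        self.alpha = alpha
        self.ci_method = ci_method
        self.random_state = random_state
        self.q = None
        self.link = None

    def fit(self, X, y, X_unlabeled=None):
        if X_unlabeled is None:
            raise ValueError("NoDebias requires X_unlabeled")
        X, y = _validate(X, y)
        Xu = _validate(X_unlabeled, name="X_unlabeled")
        est = self._resolve_estimand(X)
        seed = _as_seed(self.random_state)
        learner = self.learner if self.learner is not None else BoostedTreeLearner()
        folds = assign_folds(len(y), self.K, seed)
        bundle = fit_crossfit(X, y, Xu, folds, learner)
        Xud = _design(Xu, self.design_cols) if est.uses_features else None
        point = heuristic_no_debias(bundle, est, Xud)
        n, N = len(y), Xu.shape[0]
        self.estimand_ = est
        self.theta_ = point.theta
        self.point_estimate_ = point
        self.bundle_ = bundle
        self.n_, self.N_ = n, N
        self.confidence_set_ = None
        # CLT over the N conditionally independent imputed rows
        G = gradient(est, point.theta, Xud, bundle.unl_pred_avg)
        V = _cov(G)
        H = estimate_hessian(None, Xud, est, point.theta) if est.uses_features \
            else hessian_contrib(est, point.theta, None)
        cov = assemble_sandwich(np.zeros_like(V), V, H, N, N)
        self.covariance_ = cov
        self.se_ = np.array([np.sqrt(cov.sandwich[i, i] / N) for i in est.coords])
        self._store_cis(self._wald_like_cis(point.theta, cov, N, est))
        return self
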