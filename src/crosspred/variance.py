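"""Bootstrap estimation of the asymptotic covariance.

The asymptotic covariance of the debiased estimator has the sandwich form
``H^-1 V H^-1`` with ``V = (n/N) Sigma_theta + Sigma_Delta``, where both
covariances involve the *average model* — the expectation of the trained
predictor over training sets — which is not directly observable.  It is
approximated by training B models on bootstrap resamples of the labeled data
(each of the same size as a cross-fitting training set, ``n - floor(n/K)``)
and averaging their predictions:

* ``Sigma_theta`` is the covariance, over the unlabeled rows, of the loss
  gradient evaluated at the bootstrap-averaged predictions;
* ``Sigma_Delta`` is the covariance of the gradient *difference*
  (predicted minus true label), pooled over each resample's never-drawn
  labeled rows.  Here the models are deliberately NOT averaged, so that each
  labeled point is independent of the model it is paired with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimands import Estimand, gradient, hessian_contrib

logger = logging.getLogger(__name__)

#: eigenvalues above this (negative) floor are treated as roundoff and clipped
PSD_TOL = -1e-10


@dataclass
class BootstrapBundle:
    """B bootstrap-trained models with cached predictions.

    ``pred_lab[b]`` holds model b's predictions on *all* labeled rows (only
    the holdout entries are ever consumed); ``avg_pred_unl`` is the
    bootstrap proxy for the average model's predictions on the unlabeled
    features.
    """

    B: int
    models: list
    resamples: list[np.ndarray]
    holdouts: list[np.ndarray]
    pred_lab: np.ndarray   # (B, n)
    pred_unl: np.ndarray   # (B, N)
    avg_pred_unl: np.ndarray  # (N,)
    n_skipped: int = 0


def fit_bootstrap_models(X: np.ndarray, y: np.ndarray, X_unlabeled: np.ndarray,
                         K: int, B: int, learner, seed: int,
                         boot_mode: str = "replacement") -> BootstrapBundle:
    """Train B models on seeded resamples of size ``n - floor(n/K)``.

    ``boot_mode="replacement"`` draws with replacement (the bootstrap);
    ``"subsample"`` draws without replacement.  The holdout of resample b is
    the set of labeled rows it never drew; a resample with an empty holdout
    is skipped with a warning (an all-skipped run is an error).
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    if boot_mode not in ("replacement", "subsample"):
        raise ValueError(f"unknown boot_mode {boot_mode!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xu = np.asarray(X_unlabeled, dtype=float)
    n = len(y)
    m = n - n // K
    if m < 2:
        raise ValueError("resample size n - floor(n/K) must be >= 2")

    rng = np.random.default_rng(seed)
    models, resamples, holdouts, preds_lab, preds_unl = [], [], [], [], []
    n_skipped = 0
    for b in range(B):
        idx = rng.choice(n, size=m, replace=(boot_mode == "replacement"))
        holdout = np.setdiff1d(np.arange(n), idx)
        if holdout.size == 0:
            n_skipped += 1
            warnings.warn(f"bootstrap resample {b} covered every labeled row; skipping")
            continue
        model = learner.fit(X[idx], y[idx], seed=seed + 1 + b)
        models.append(model)
        resamples.append(idx)
        holdouts.append(holdout)
        preds_lab.append(np.asarray(model.predict(X), dtype=float))
        preds_unl.append(np.asarray(model.predict(Xu), dtype=float))
    if not models:
        raise RuntimeError("all bootstrap resamples were degenerate (empty holdouts)")
    pred_lab = np.vstack(preds_lab)
    pred_unl = np.vstack(preds_unl)
    logger.info("bootstrap: trained %d/%d models (%d skipped)", len(models), B, n_skipped)
    return BootstrapBundle(B=len(models), models=models, resamples=resamples,
                           holdouts=holdouts, pred_lab=pred_lab, pred_unl=pred_unl,
                           avg_pred_unl=pred_unl.mean(axis=0), n_skipped=n_skipped)


def _cov(G: np.ndarray) -> np.ndarray:
    """Empirical covariance of gradient rows, unbiased denominator."""
    G = np.atleast_2d(G)
    if G.shape[0] < 2:
        raise ValueError("need at least 2 rows for a covariance estimate")
    return np.atleast_2d(np.cov(G, rowvar=False, ddof=1))


def estimate_sigma_theta(boot: BootstrapBundle, X_unl_design: np.ndarray | None,
                         estimand: Estimand, theta: np.ndarray) -> np.ndarray:
    """Covariance over unlabeled rows of gradients at bootstrap-averaged predictions."""
    if boot.avg_pred_unl.shape[0] < 2:
        raise ValueError("need at least 2 unlabeled rows")
    G = gradient(estimand, theta, X_unl_design, boot.avg_pred_unl)
    return _cov(G)


def estimate_sigma_delta(boot: BootstrapBundle, X_design: np.ndarray | None,
                         y: np.ndarray, estimand: Estimand,
                         theta: np.ndarray) -> np.ndarray:
    """Covariance of per-model gradient differences over pooled holdout rows.

    The pooled collection is {(b, i) : i in holdout(b)}; model b is never
    averaged with the others here, keeping each labeled point independent of
    the model it is differenced against.
    """
    diffs = []
    for b, hold in enumerate(boot.holdouts):
        Xh = None if X_design is None else X_design[hold]
        g_pred = gradient(estimand, theta, Xh, boot.pred_lab[b, hold])
        g_true = gradient(estimand, theta, Xh, y[hold])
        diffs.append(np.atleast_2d(g_pred - g_true))
    D = np.vstack(diffs)
    if D.shape[0] < 2:
        raise ValueError("fewer than 2 pooled holdout pairs; increase B or n")
    return _cov(D)


def estimate_hessian(X_design: np.ndarray | None, X_unl_design: np.ndarray | None,
                     estimand: Estimand, theta: np.ndarray) -> np.ndarray:
    """Plug-in Hessian: average per-observation Hessian over pooled features."""
    if estimand.kind == "mean":
        return hessian_contrib(estimand, theta, None)
    parts = [M for M in (X_design, X_unl_design) if M is not None]
    pooled = np.vstack(parts)
    return hessian_contrib(estimand, np.atleast_1d(theta), pooled)


@dataclass
class CovarianceEstimate:
    """Assembled sandwich covariance and its ingredients.

    ``sandwich`` estimates the asymptotic covariance of ``sqrt(n) (theta_hat
    - theta*)``; per-coordinate standard errors are
    ``sqrt(sandwich[i, i] / n)``.
    """

    sigma_theta: np.ndarray
    sigma_delta: np.ndarray
    hessian: np.ndarray
    v_hat: np.ndarray
    sandwich: np.ndarray
    n: int
    N: int
    clip_events: dict = field(default_factory=dict)


def _symmetrize_psd(M: np.ndarray, name: str, events: dict) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() < 0:
        if w.min() < PSD_TOL * max(1.0, abs(w).max()):
            warnings.warn(f"{name}: clipping eigenvalue {w.min():.3e} to 0")
        events[name] = float(w.min())
        w = np.clip(w, 0.0, None)
        M = (V * w) @ V.T
    return 0.5 * (M + M.T)


def assemble_sandwich(sigma_theta: np.ndarray, sigma_delta: np.ndarray,
                      hessian: np.ndarray, n: int, N: int) -> CovarianceEstimate:
    """Combine the pieces: ``V = (n/N) Sigma_theta + Sigma_Delta``,
    ``Sigma = H^-1 V H^-1`` (symmetrized, PSD-clipped)."""
    events: dict = {}
    st = _symmetrize_psd(np.atleast_2d(sigma_theta), "sigma_theta", events)
    sd = _symmetrize_psd(np.atleast_2d(sigma_delta), "sigma_delta", events)
    H = 0.5 * (np.atleast_2d(hessian) + np.atleast_2d(hessian).T)
    v_hat = _symmetrize_psd((n / N) * st + sd, "v_hat", events)
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"Hessian is numerically singular (cond={cond:.3e})")
    Hinv = np.linalg.inv(H)
    sandwich = _symmetrize_psd(Hinv @ v_hat @ Hinv, "sandwich", events)
    return CovarianceEstimate(sigma_theta=st, sigma_delta=sd, hessian=H,
                              v_hat=v_hat, sandwich=sandwich, n=n, N=N,
                              clip_events=events)
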