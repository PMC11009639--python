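"""Loss families defining the estimation targets.

Every target handled by this package is an M-estimand: the minimizer of an
expected convex loss ``E[l_theta(X, Y)]``.  Four families are supported:

``mean``
    squared loss ``(y - theta)^2``; the target is ``E[Y]``.
``quantile``
    pinball loss at level ``q``; the target is the ``q``-quantile of ``Y``.
``ols``
    half squared error ``(y - x' theta)^2 / 2``; the target is the population
    least-squares coefficient vector.
``glm``
    exponential-family negative log-likelihood ``-y x'theta + psi(x'theta)``
    with a convex log-partition ``psi`` (identity link: ``psi(s) = s^2/2``,
    which reproduces OLS; logistic link: ``psi(s) = log(1 + e^s)``).

The gradient and per-observation Hessian of each loss are the ingredients of
both the debiased point estimators and the sandwich covariance, so they are
exposed vectorized over rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit


class EstimandConfigError(ValueError):
    """Inconsistent estimand configuration (missing q/link, bad dimension)."""


class UnsupportedOperationError(RuntimeError):
    """Operation not defined for this loss family (e.g. quantile Hessian)."""


_KINDS = ("mean", "quantile", "ols", "glm")
_LINKS = ("identity", "logistic")


@dataclass(frozen=True)
class Estimand:
    """Specification of one M-estimation target.

    Parameters
    ----------
    kind : {"mean", "quantile", "ols", "glm"}
        Loss family.
    d : int
        Parameter dimension; forced to 1 for mean and quantile targets.
    q : float, optional
        Quantile level in (0, 1); required iff ``kind == "quantile"``.
    link : {"identity", "logistic"}, optional
        Log-partition choice; required iff ``kind == "glm"``.
    target_coords : tuple of int, optional
        0-based coordinates reported in summaries; defaults to all of them.
    """

    kind: str
    d: int = 1
    q: float | None = None
    link: str | None = None
    target_coords: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise EstimandConfigError(f"unknown estimand kind {self.kind!r}")
        if self.kind in ("mean", "quantile") and self.d != 1:
            raise EstimandConfigError(f"{self.kind} estimand requires d=1, got d={self.d}")
        if self.d < 1:
            raise EstimandConfigError("d must be a positive integer")
        if self.kind == "quantile":
            if self.q is None or not (0.0 < self.q < 1.0):
                raise EstimandConfigError("quantile estimand needs q in (0, 1)")
        elif self.q is not None:
            raise EstimandConfigError("q is only meaningful for quantile estimands")
        if self.kind == "glm":
            if self.link not in _LINKS:
                raise EstimandConfigError(f"glm estimand needs link in {_LINKS}")
        elif self.link is not None:
            raise EstimandConfigError("link is only meaningful for glm estimands")
        if self.target_coords is not None:
            coords = tuple(int(c) for c in self.target_coords)
            if any(c < 0 or c >= self.d for c in coords):
                raise EstimandConfigError("target_coords out of range")
            object.__setattr__(self, "target_coords", coords)

    @property
    def coords(self) -> tuple[int, ...]:
        return self.target_coords if self.target_coords is not None else tuple(range(self.d))

    @property
    def uses_features(self) -> bool:
        return self.kind in ("ols", "glm")


def make_estimand(kind: str, *, d: int | None = None, q: float | None = None,
                  link: str | None = None,
                  target_coords: tuple[int, ...] | None = None) -> Estimand:
    """Build an :class:`Estimand` from loose config keys."""
    if d is None:
        d = 1
    return Estimand(kind=kind, d=int(d), q=q, link=link, target_coords=target_coords)


# ---------------------------------------------------------------------------
# link functions (log-partition psi and its derivatives)

def _psi(link: str, s: np.ndarray) -> np.ndarray:
    if link == "identity":
        return 0.5 * s ** 2
    return np.logaddexp(0.0, s)  # log(1 + e^s), stable for large |s|


def _psi_prime(link: str, s: np.ndarray) -> np.ndarray:
    return s if link == "identity" else expit(s)


def _psi_double_prime(link: str, s: np.ndarray) -> np.ndarray:
    if link == "identity":
        return np.ones_like(s)
    p = expit(s)
    return p * (1.0 - p)


def _check_inputs(estimand: Estimand, theta: np.ndarray,
                  x: np.ndarray | None) -> tuple[np.ndarray, np.ndarray | None]:
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if theta.shape != (estimand.d,):
        raise ValueError(f"theta must have shape ({estimand.d},), got {theta.shape}")
    if estimand.uses_features:
        if x is None:
            raise ValueError(f"{estimand.kind} estimand requires features x")
        x = np.asarray(x, dtype=float)
        x2 = np.atleast_2d(x)
        if x2.shape[-1] != estimand.d:
            raise ValueError(f"features must have {estimand.d} columns, got {x2.shape[-1]}")
        return theta, x2
    return theta, None


def loss(estimand: Estimand, theta: np.ndarray, x: np.ndarray | None,
         y: np.ndarray | float) -> np.ndarray:
    """Per-observation loss; vectorized over rows of ``x`` / entries of ``y``."""
    theta, X = _check_inputs(estimand, theta, x)
    y = np.asarray(y, dtype=float)
    if estimand.kind == "mean":
        return np.squeeze((y - theta[0]) ** 2)
    if estimand.kind == "quantile":
        q, t = estimand.q, theta[0]
        return np.squeeze(np.where(y > t, q * (y - t), (1.0 - q) * (t - y)))
    s = X @ theta
    if estimand.kind == "ols":
        return np.squeeze(0.5 * (y - s) ** 2)
    return np.squeeze(-y * s + _psi(estimand.link, s))


def gradient(estimand: Estimand, theta: np.ndarray, x: np.ndarray | None,
             y: np.ndarray | float) -> np.ndarray:
    """Per-observation loss gradient, shape ``(m, d)`` (or ``(d,)`` for one row).

    The pinball subgradient at a tie ``y == theta`` takes the closed-half
    convention ``-q + 1{y <= theta}``, i.e. the value ``1 - q``.
    """
    theta, X = _check_inputs(estimand, theta, x)
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    scalar = np.ndim(y) == 0 and (x is None or np.ndim(x) <= 1)
    if estimand.kind == "mean":
        g = 2.0 * (theta[0] - y_arr)[:, None]
    elif estimand.kind == "quantile":
        g = (-estimand.q + (y_arr <= theta[0]).astype(float))[:, None]
    else:
        s = X @ theta
        resid = _psi_prime(estimand.link, s) - y_arr if estimand.kind == "glm" else s - y_arr
        g = resid[:, None] * X
    return g[0] if scalar else g


def hessian_contrib(estimand: Estimand, theta: np.ndarray,
                    x: np.ndarray | None) -> np.ndarray:
    """Per-observation Hessian contribution.

    Returns a ``(d, d)`` matrix for a single feature row or the *average*
    over rows when ``x`` is 2-D (mean family: the scalar 2 as a 1x1 matrix).
    Quantile targets have no usable Hessian (inference goes through CDF
    inversion) and raise :class:`UnsupportedOperationError`.
    """
    if estimand.kind == "quantile":
        raise UnsupportedOperationError("quantile estimand has no Hessian; use CDF inversion")
    theta, X = _check_inputs(estimand, theta, x)
    if estimand.kind == "mean":
        return np.array([[2.0]])
    single = np.ndim(x) == 1
    if estimand.kind == "ols":
        w = np.ones(X.shape[0])
    else:
        w = _psi_double_prime(estimand.link, X @ theta)
    H = (X * w[:, None]).T @ X
    if not single:
        H /= X.shape[0]
    return H
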