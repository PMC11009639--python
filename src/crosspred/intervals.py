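"""Confidence interval and confidence set construction.

Two routes are provided, matching the two asymptotic results the estimators
satisfy:

* Wald intervals ``theta_i ± z * sqrt(Sigma_ii / n)`` from the CLT for the
  point estimator, with an optional Bonferroni correction over coordinates;
* test inversion: the set of all theta at which the normalized debiased
  score ``||V_theta^{-1/2} grad L+(theta)||^2`` stays below the chi-squared
  quantile.  For quantile targets the score is a corrected empirical CDF
  minus the level q, which makes the inversion exact on the step grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .variance import CovarianceEstimate


@dataclass
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    coordinate: int = 0
    method: str = "wald"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower endpoint exceeds upper endpoint")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass
class ConfidenceSet:
    """Grid-based acceptance region from inverting the score test."""

    grid: np.ndarray
    statistics: np.ndarray
    accepted: np.ndarray  # boolean mask
    threshold: float
    level: float
    hull: ConfidenceInterval | None
    disconnected: bool = False
    n_indeterminate: int = 0

    @property
    def empty(self) -> bool:
        return not bool(self.accepted.any())


def _zq(alpha: float, d: int = 1) -> float:
    return float(stats.norm.ppf(1.0 - alpha / (2 * d)))


def wald_ci(theta_hat: np.ndarray, cov: CovarianceEstimate, n: int,
            alpha: float, coordinate: int = 0) -> ConfidenceInterval:
    """Per-coordinate CLT interval ``theta_i ± z_{1-a/2} sqrt(Sigma_ii / n)``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    theta_hat = np.atleast_1d(theta_hat)
    var = cov.sandwich[coordinate, coordinate]
    if var < 0:
        raise FloatingPointError("negative variance after PSD clipping")
    half = _zq(alpha) * np.sqrt(var / n)
    t = float(theta_hat[coordinate])
    return ConfidenceInterval(t - half, t + half, 1 - alpha, coordinate,
                              method="wald", degenerate=half == 0.0)


def bonferroni_cis(theta_hat: np.ndarray, cov: CovarianceEstimate, n: int,
                   alpha: float) -> list[ConfidenceInterval]:
    """Simultaneous per-coordinate intervals at level alpha/(2d)."""
    theta_hat = np.atleast_1d(theta_hat)
    d = theta_hat.shape[0]
    z = _zq(alpha, d)
    out = []
    for i in range(d):
        half = z * np.sqrt(cov.sandwich[i, i] / n)
        out.append(ConfidenceInterval(theta_hat[i] - half, theta_hat[i] + half,
                                      1 - alpha, i, method="bonferroni",
                                      degenerate=half == 0.0))
    return out


def invert_gradient_test(grid: np.ndarray,
                         grad_fn: Callable[[np.ndarray], np.ndarray],
                         vtheta_fn: Callable[[np.ndarray], np.ndarray],
                         n: int, d: int, alpha: float) -> ConfidenceSet:
    """Score-test inversion over a grid of candidate parameter values.

    A candidate theta is accepted when
    ``grad' V_theta^{-1} grad <= chi2_{d, 1-alpha} / n``.  Grid points with a
    numerically singular ``V_theta`` are marked indeterminate and excluded.
    For ``d == 1`` the grid is a 1-D array and the hull is an interval.
    """
    grid = np.asarray(grid, dtype=float)
    thresh = float(stats.chi2.ppf(1.0 - alpha, df=d)) / n
    G = grid.shape[0]
    statistics = np.full(G, np.inf)
    indeterminate = 0
    for g in range(G):
        theta = np.atleast_1d(grid[g])
        grad = np.atleast_1d(grad_fn(theta))
        V = np.atleast_2d(vtheta_fn(theta))
        try:
            statistics[g] = float(grad @ np.linalg.solve(V, grad))
        except np.linalg.LinAlgError:
            indeterminate += 1
    accepted = statistics <= thresh
    hull, disconnected = None, False
    if accepted.any() and grid.ndim == 1:
        idx = np.flatnonzero(accepted)
        hull = ConfidenceInterval(float(grid[idx[0]]), float(grid[idx[-1]]),
                                  1 - alpha, method="invert")
        disconnected = bool((np.diff(idx) > 1).any())
    return ConfidenceSet(grid=grid, statistics=statistics, accepted=accepted,
                         threshold=thresh, level=1 - alpha, hull=hull,
                         disconnected=disconnected, n_indeterminate=indeterminate)


def quantile_ci(cdf, sigma_theta_eval: Callable[[np.ndarray], np.ndarray],
                sigma_delta_eval: Callable[[np.ndarray], np.ndarray],
                n: int, N: int, q: float, alpha: float) -> ConfidenceSet:
    """CDF-inversion confidence set for a quantile target.

    Accepts every grid value theta with
    ``|F+(theta) - Delta+(theta) - q| <= z_{1-a/2} sqrt(s_t^2/N + s_d^2/n)``
    where the variance evaluators return the indicator variances at each grid
    point.  ``n`` is the effective labeled count behind the debiasing term
    and ``N`` the unlabeled count (``N=inf``-like behavior is obtained by a
    zero ``sigma_theta_eval``).  The reported interval is the convex hull of
    the accepted step grid, flagged if the accepted set has gaps.
    """
    grid = cdf.grid
    corrected = cdf.corrected
    st2 = np.asarray(sigma_theta_eval(grid), dtype=float)
    sd2 = np.asarray(sigma_delta_eval(grid), dtype=float)
    half = _zq(alpha) * np.sqrt(st2 / N + sd2 / n)
    score = corrected - q
    accepted = np.abs(score) <= half
    statistics = np.where(half > 0, (score / np.where(half == 0, np.inf, half)) ** 2,
                          np.where(score == 0, 0.0, np.inf))
    hull, disconnected = None, False
    if accepted.any():
        idx = np.flatnonzero(accepted)
        hull = ConfidenceInterval(float(grid[idx[0]]), float(grid[idx[-1]]),
                                  1 - alpha, method="cdf-inversion")
        disconnected = bool((np.diff(idx) > 1).any())
    return ConfidenceSet(grid=grid, statistics=statistics, accepted=accepted,
                         threshold=1.0, level=1 - alpha, hull=hull,
                         disconnected=disconnected)
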