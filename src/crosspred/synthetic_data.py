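"""Synthetic data-generating processes with tunable signal strength.

Two Gaussian linear families drive all simulation studies:

* ``mean_quantile`` — two standard-normal features, outcome
  ``Y = mu + X'beta + xi`` with ``beta1 = beta2 = R * sigma_Y / sqrt(2)``
  and ``xi ~ N(0, sigma_Y^2 (1 - R^2))``.  The scaling makes two things
  hold simultaneously: ``R^2 = Var(X'beta) / Var(Y)`` (the explained
  variance) and ``Var(Y) = sigma_Y^2`` regardless of R, so the classical
  interval width is R-free and any power gain is attributable to the
  predictions.  Targets: the mean (``mu``) and any quantile
  (``mu + sigma_Y * Phi^{-1}(q)``, since Y is Gaussian).
* ``linreg`` — three standard-normal features, ``Y = X'beta + xi`` with
  ``beta = (1, 1, R0 * sigma_Y)`` and ``xi ~ N(0, sigma_Y^2 (1 - R0^2))``.
  The inference target is the least-squares coefficient of X1 when
  regressing Y on (X1, X2) only; because X3 is independent of (X1, X2) the
  population value is exactly ``beta1 = 1``.  Learners see all three
  features, so the excluded-but-predictive X3 helps the imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimands import Estimand

_FAMILIES = ("mean_quantile", "linreg")


@dataclass(frozen=True)
class DGPConfig:
    """Configuration of one synthetic data-generating process.

    ``r`` is the signal level: R for the mean/quantile family (explained
    standard-deviation fraction, R^2 explained variance), R0 for linreg.
    ``beta_scale`` selects the beta normalization of the mean/quantile
    family: ``"sqrt2"`` (default) sets ``beta1 = beta2 = R sigma_Y/sqrt(2)``
    so that R^2 is exactly the explained variance; ``"half"`` uses
    ``R sigma_Y / 2`` instead.
    """

    family: str = "mean_quantile"
    n: int = 100
    N: int = 10_000
    r: float = 0.5
    mu: float = 4.0
    sigma_y2: float = 4.0
    seed: int = 0
    beta_scale: str = "sqrt2"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("signal level r must lie in [0, 1]")
        if self.sigma_y2 <= 0:
            raise ValueError("sigma_y2 must be positive")
        if self.beta_scale not in ("sqrt2", "half"):
            raise ValueError("beta_scale must be 'sqrt2' or 'half'")


@dataclass
class SyntheticDataset:
    """A labeled (X, y) plus unlabeled (X_unlabeled) draw and its ground truth."""

    X: np.ndarray
    y: np.ndarray
    X_unlabeled: np.ndarray
    config: DGPConfig
    design_cols: tuple[int, ...] | None = None

    def truth(self, estimand: Estimand | str, q: float | None = None) -> float:
        """Population value of the named target under this DGP."""
        kind = estimand.kind if isinstance(estimand, Estimand) else estimand
        cfg = self.config
        if cfg.family == "mean_quantile":
            sigma = math.sqrt(cfg.sigma_y2)
            if kind == "mean":
                return cfg.mu
            if kind == "quantile":
                level = estimand.q if isinstance(estimand, Estimand) else q
                return cfg.mu + sigma * float(stats.norm.ppf(level))
            raise ValueError(f"no ground truth for {kind!r} under this family")
        if kind == "ols":
            return 1.0  # coefficient of X1 in the population regression on (X1, X2)
        raise ValueError(f"no ground truth for {kind!r} under the linreg family")


def _beta_mean_family(cfg: DGPConfig) -> np.ndarray:
    sigma = math.sqrt(cfg.sigma_y2)
    denom = math.sqrt(2.0) if cfg.beta_scale == "sqrt2" else 2.0
    return np.full(2, cfg.r * sigma / denom)


def generate_mean_dgp(cfg: DGPConfig) -> SyntheticDataset:
    """Draw labeled and unlabeled samples from the mean/quantile family."""
    if cfg.family != "mean_quantile":
        raise ValueError("config family must be 'mean_quantile'")
    rng = np.random.default_rng(cfg.seed)
    beta = _beta_mean_family(cfg)
    noise_sd = math.sqrt(cfg.sigma_y2 * (1.0 - cfg.r ** 2))
    X = rng.standard_normal((cfg.n, 2))
    y = cfg.mu + X @ beta + noise_sd * rng.standard_normal(cfg.n)
    Xu = rng.standard_normal((cfg.N, 2))
    return SyntheticDataset(X=X, y=y, X_unlabeled=Xu, config=cfg)


def generate_linreg_dgp(cfg: DGPConfig) -> SyntheticDataset:
    """Draw from the linear-regression family (3 features, design on the first 2)."""
    if cfg.family != "linreg":
        raise ValueError("config family must be 'linreg'")
    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(cfg.sigma_y2)
    beta = np.array([1.0, 1.0, cfg.r * sigma])
    noise_sd = math.sqrt(cfg.sigma_y2 * (1.0 - cfg.r ** 2))
    X = rng.standard_normal((cfg.n, 3))
    y = X @ beta + noise_sd * rng.standard_normal(cfg.n)
    Xu = rng.standard_normal((cfg.N, 3))
    return SyntheticDataset(X=X, y=y, X_unlabeled=Xu, config=cfg,
                            design_cols=(0, 1))


def generate(cfg: DGPConfig) -> SyntheticDataset:
    """Dispatch on ``cfg.family``."""
    if cfg.family == "mean_quantile":
        return generate_mean_dgp(cfg)
    return generate_linreg_dgp(cfg)
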