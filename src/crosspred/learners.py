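"""Black-box learner plug-ins.

The inference machinery treats the predictive model as a black box satisfying
a minimal contract: a learner is any object with

    ``fit(X, y, seed) -> model``      (a fresh fitted model; the learner
                                       itself holds no state)
    ``model.predict(X) -> ndarray``   (pure: same input, same output)

Two adapters cover the common cases: :class:`BoostedTreeLearner` wraps
XGBoost regression with library defaults, and :class:`LinearLearner` is an
ordinary least-squares fit (with intercept).  :class:`ConstantLearner` and
:class:`BiasedLearner` exist mainly for diagnostics and tests — a constant
predictor makes the debiased estimator collapse to the classical one, and a
deliberately offset predictor exhibits the failure mode of skipping the
debiasing step.
"""

from __future__ import annotations

import numpy as np


class _LinearModel:
    def __init__(self, coef: np.ndarray, intercept: float):
        self._coef = coef
        self._intercept = intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self._coef + self._intercept


class LinearLearner:
    """Ordinary least-squares learner (intercept included). Deterministic."""

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int | None = None) -> _LinearModel:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        A = np.column_stack([np.ones(len(X)), X])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        return _LinearModel(beta[1:], beta[0])

    def __repr__(self) -> str:  # pragma: no cover
        return "LinearLearner()"


class _BoosterModel:
    def __init__(self, booster):
        self._booster = booster

    def predict(self, X: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        return self._booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)))


class BoostedTreeLearner:
    """Gradient-boosted regression trees via the native XGBoost training API.

    Both the booster parameters and the number of boosting rounds are left
    at the library's defaults; ``params`` and ``num_boost_round`` override
    them.  The per-fit ``seed`` controls the booster's internal randomness.
    """

    def __init__(self, num_boost_round: int | None = None, **params):
        self.num_boost_round = num_boost_round
        self.params = params

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int | None = None) -> _BoosterModel:
        import xgboost as xgb

        dtrain = xgb.DMatrix(np.asarray(X, dtype=float),
                             label=np.asarray(y, dtype=float))
        params = {"seed": 0 if seed is None else int(seed), "nthread": 1,
                  **self.params}
        kwargs = {}
        if self.num_boost_round is not None:
            kwargs["num_boost_round"] = self.num_boost_round
        return _BoosterModel(xgb.train(params, dtrain, **kwargs))

    def __repr__(self) -> str:  # pragma: no cover
        return "BoostedTreeLearner()"


class _ConstantModel:
    def __init__(self, c: float):
        self._c = float(c)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], self._c)


class ConstantLearner:
    """Predicts a fixed constant regardless of the data."""

    def __init__(self, c: float):
        self.c = float(c)

    def fit(self, X, y, seed: int | None = None) -> _ConstantModel:
        return _ConstantModel(self.c)


class _OffsetModel:
    def __init__(self, base, offset: float):
        self._base = base
        self._offset = offset

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._base.predict(X) + self._offset


class BiasedLearner:
    """Wraps another learner and adds a constant offset to its predictions.

    Useful for demonstrating that un-debiased imputation inherits any
    systematic prediction bias.
    """

    def __init__(self, base, offset: float):
        self.base = base
        self.offset = float(offset)

    def fit(self, X, y, seed: int | None = None) -> _OffsetModel:
        return _OffsetModel(self.base.fit(X, y, seed), self.offset)


def get_learner(name: str):
    """Resolve a learner by CLI-friendly name."""
    table = {"xgboost": BoostedTreeLearner, "boosted-tree": BoostedTreeLearner,
             "linear": LinearLearner}
    try:
        return table[name]()
    except KeyError:
        raise ValueError(f"unknown learner {name!r}; choose from {sorted(table)}") from None
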