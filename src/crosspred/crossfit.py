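"""Fold management and cross-fitting.

The labeled data are split into K folds; model j is trained on all folds
except fold j, so each labeled point has one prediction made by a model that
never saw it (its out-of-fold prediction), and each unlabeled point has K
predictions whose average is the imputation actually used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic partition of ``range(n)`` into K near-equal folds.

    Indices are randomly permuted under ``seed`` and then cut into
    contiguous blocks; the remainder ``n mod K`` is spread over the first
    folds, so fold sizes differ by at most one.
    """

    n: int
    K: int
    fold_of: np.ndarray  # length n, values in {0..K-1}
    seed: int

    def indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == j)

    def complement(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != j)


def assign_folds(n: int, K: int, seed: int) -> FoldAssignment:
    """Assign each of ``n`` labeled rows to one of ``K`` folds.

    Raises
    ------
    ValueError
        If ``K < 2`` or ``K > n``.
    """
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, K)
    sizes = np.full(K, base)
    sizes[:rem] += 1
    fold_of = np.empty(n, dtype=np.int64)
    start = 0
    for j, size in enumerate(sizes):
        fold_of[perm[start:start + size]] = j
        start += size
    return FoldAssignment(n=n, K=K, fold_of=fold_of, seed=seed)


@dataclass
class CrossFitBundle:
    """K fold-excluded models plus all predictions the estimators need.

    Attributes
    ----------
    models : list
        ``models[j]`` was trained with fold ``j`` held out.
    folds : FoldAssignment
    oof_pred : ndarray, shape (n,)
        ``oof_pred[i] = models[fold_of[i]].predict(X[i])`` — the prediction
        for labeled row i by the model that did not train on it.
    unl_pred : ndarray, shape (K, N)
        Row j holds model j's predictions on the unlabeled features.
    unl_pred_avg : ndarray, shape (N,)
        Mean over the K models, the imputed labels for the unlabeled rows.
    """

    models: list
    folds: FoldAssignment
    oof_pred: np.ndarray
    unl_pred: np.ndarray
    unl_pred_avg: np.ndarray

    @property
    def K(self) -> int:
        return self.folds.K


def fit_crossfit(X: np.ndarray, y: np.ndarray, X_unlabeled: np.ndarray,
                 folds: FoldAssignment, learner) -> CrossFitBundle:
    """Train the K fold-excluded models and collect their predictions.

    Per-fold learner seeds are ``folds.seed + j`` so the K fits are
    reproducible but not identical for stochastic learners.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xu = np.asarray(X_unlabeled, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if X.ndim != 2 or Xu.ndim != 2 or X.shape[1] != Xu.shape[1]:
        raise ValueError("labeled and unlabeled feature dimensions must agree")
    if folds.n != n:
        raise ValueError("fold assignment was built for a different n")

    K, N = folds.K, Xu.shape[0]
    models = []
    oof_pred = np.empty(n)
    unl_pred = np.empty((K, N))
    for j in range(K):
        train = folds.complement(j)
        try:
            model = learner.fit(X[train], y[train], seed=folds.seed + j)
        except Exception as exc:
            raise RuntimeError(f"learner failed on fold {j}") from exc
        models.append(model)
        logger.info("cross-fit: fold %d/%d trained on %d rows", j + 1, K, len(train))
        hold = folds.indices(j)
        oof_pred[hold] = np.asarray(model.predict(X[hold]), dtype=float)
        unl_pred[j] = np.asarray(model.predict(Xu), dtype=float)
    return CrossFitBundle(models=models, folds=folds,
                          oof_pred=oof_pred, unl_pred=unl_pred,
                          unl_pred_avg=unl_pred.mean(axis=0))
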