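import numpy as np
import pytest

from crosspred import CrossFitBundle, LinearLearner, assign_folds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_labeled():
    """Four labeled rows with outcomes (1, 2, 3, 4) and trivial features."""
    X = np.arange(8, dtype=float).reshape(4, 2)
    y = np.array([1.0, 2.0, 3.0, 4.0])
    return X, y


def make_constant_bundle(y, c_by_fold, X, Xu, seed=0):
    """Bundle whose model j predicts the constant c_by_fold[j] everywhere."""
    K = len(c_by_fold)
    folds = assign_folds(len(y), K, seed)
    oof = np.array([c_by_fold[folds.fold_of[i]] for i in range(len(y))], dtype=float)
    unl = np.tile(np.asarray(c_by_fold, dtype=float)[:, None], (1, len(Xu)))
    models = [None] * K
    return CrossFitBundle(models=models, folds=folds, oof_pred=oof,
                          unl_pred=unl, unl_pred_avg=unl.mean(axis=0))


@pytest.fixture
def linear_learner():
    return LinearLearner()
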