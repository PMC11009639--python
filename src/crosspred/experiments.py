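"""Trial runner: coverage, width, and endpoint-stability simulation studies.

Runs repeated draws from a synthetic DGP, fits a set of inference methods on
each draw, and summarizes per method the empirical coverage of the true
target, the mean interval width, and the standard deviations of the interval
endpoints across trials (the stability measure).  Trial t derives every
source of randomness — the data draw, fold assignment, learner fits,
bootstrap resamples, and the PPI split — from ``seed + t``, so a summary is
bitwise reproducible for deterministic learners.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import (ClassicalInference, CrossPrediction, NoDebias,
                         NoFolds, PPI)
from .learners import BoostedTreeLearner
from .synthetic_data import DGPConfig, generate

logger = logging.getLogger(__name__)

METHODS = ("crosspred", "classical", "ppi", "no_debias", "no_folds")


@dataclass
class TrialRecord:
    trial: int
    method: str
    theta: float
    lower: float
    upper: float
    covered: bool


@dataclass
class SimulationSummary:
    """Per-method coverage / width / endpoint-SD table plus raw records."""

    estimand: str
    truth: float
    n_trials: int
    methods: dict[str, dict] = field(default_factory=dict)
    records: pd.DataFrame | None = None
    n_failures: int = 0

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(self.methods).T

    def to_dict(self) -> dict:
        return {"estimand": self.estimand, "truth": self.truth,
                "n_trials": self.n_trials, "n_failures": self.n_failures,
                "methods": self.methods}


def _make_method(method: str, estimand: str, q: float, design_cols,
                 alpha: float, K: int, B: int, learner, train_fraction: float,
                 seed: int):
    common = dict(design_cols=design_cols, alpha=alpha, random_state=seed)
    if method == "crosspred":
        return CrossPrediction(estimand, q=q, K=K, B=B, learner=learner, **common)
    if method == "classical":
        return ClassicalInference(estimand, q=q, **common)
    if method == "ppi":
        return PPI(estimand, q=q, train_fraction=train_fraction,
                   learner=learner, **common)
    if method == "no_debias":
        return NoDebias(estimand, K=K, learner=learner, **common)
    if method == "no_folds":
        return NoFolds(estimand, learner=learner, **common)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def run_trials(dgp: DGPConfig, estimand: str = "mean", *, q: float = 0.75,
               methods=("crosspred", "classical", "ppi"), trials: int = 100,
               alpha: float = 0.1, K: int = 10, B: int = 30, learner=None,
               train_fraction: float = 0.5, seed: int = 0) -> SimulationSummary:
    """Run seeded independent trials and summarize each method.

    The reporting coordinate is the scalar target for mean/quantile and the
    first design coordinate for regression targets.  A trial in which a
    method raises is recorded as a failure for that method and excluded
    from its summary.
    """
    if trials < 1:
        raise ValueError("need at least one trial")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    if learner is None:
        learner = BoostedTreeLearner()

    records: list[TrialRecord] = []
    n_failures = 0
    truth = None
    for t in range(trials):
        trial_seed = seed + t
        data = generate(dataclasses.replace(dgp, seed=trial_seed))
        est_q = q if estimand == "quantile" else None
        truth = data.truth(estimand, q=est_q)
        for method in methods:
            m = _make_method(method, estimand, q, data.design_cols, alpha,
                             K, B, learner, train_fraction, trial_seed)
            try:
                m.fit(data.X, data.y, X_unlabeled=data.X_unlabeled)
                lo, hi = m.interval_
            except Exception:
                logger.exception("trial %d: method %s failed", t, method)
                n_failures += 1
                continue
            records.append(TrialRecord(trial=t, method=method,
                                       theta=float(np.atleast_1d(m.theta_)[0]
                                                   if estimand in ("mean", "quantile")
                                                   else m.theta_[0]),
                                       lower=lo, upper=hi,
                                       covered=bool(lo <= truth <= hi)))
        logger.info("trial %d/%d done", t + 1, trials)

    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    summary = SimulationSummary(estimand=estimand, truth=float(truth),
                                n_trials=trials, records=df,
                                n_failures=n_failures)
    for method in methods:
        sub = df[df["method"] == method]
        if len(sub) == 0:
            continue
        summary.methods[method] = {
            "coverage": float(sub["covered"].mean()),
            "mean_width": float((sub["upper"] - sub["lower"]).mean()),
            "mean_theta": float(sub["theta"].mean()),
            "sd_lower": float(sub["lower"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "sd_upper": float(sub["upper"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "n_ok": int(len(sub)),
        }
    return summary


def crosspred_trials(dgp: DGPConfig, estimands=("mean",), *, q: float = 0.75,
                     trials: int = 100, alpha: float = 0.1, K: int = 10,
                     B: int = 30, learner=None,
                     seed: int = 0) -> dict[str, SimulationSummary]:
    """Cross-prediction coverage trials for several estimands of one DGP.

    The cross-fit and bootstrap models depend only on the data, not on the
    estimand, so within each trial they are fitted once and reused for every
    requested estimand.  Results are identical to fitting
    :class:`~crosspred.estimators.CrossPrediction` separately per estimand
    with ``random_state = seed + t``.
    """
    from .crossfit import assign_folds, fit_crossfit
    from .variance import fit_bootstrap_models

    if learner is None:
        learner = BoostedTreeLearner()
    records: dict[str, list[TrialRecord]] = {e: [] for e in estimands}
    truths: dict[str, float] = {}
    for t in range(trials):
        trial_seed = seed + t
        data = generate(dataclasses.replace(dgp, seed=trial_seed))
        folds = assign_folds(len(data.y), K, trial_seed)
        bundle = fit_crossfit(data.X, data.y, data.X_unlabeled, folds, learner)
        boot = fit_bootstrap_models(data.X, data.y, data.X_unlabeled, K, B,
                                    learner, trial_seed + 100_000)
        for estimand in estimands:
            m = CrossPrediction(estimand, q=q, design_cols=data.design_cols,
                                K=K, B=B, learner=learner, alpha=alpha,
                                random_state=trial_seed)
            m._fit_from_bundles(data.X, data.y, data.X_unlabeled, bundle, boot)
            est_q = q if estimand == "quantile" else None
            truth = data.truth(estimand, q=est_q)
            truths[estimand] = truth
            lo, hi = m.interval_
            records[estimand].append(TrialRecord(
                trial=t, method="crosspred", theta=float(m.theta_[0]),
                lower=lo, upper=hi, covered=bool(lo <= truth <= hi)))
        logger.info("shared trial %d/%d done", t + 1, trials)

    out = {}
    for estimand in estimands:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records[estimand]])
        s = SimulationSummary(estimand=estimand, truth=truths[estimand],
                              n_trials=trials, records=df)
        s.methods["crosspred"] = {
            "coverage": float(df["covered"].mean()),
            "mean_width": float((df["upper"] - df["lower"]).mean()),
            "mean_theta": float(df["theta"].mean()),
            "sd_lower": float(df["lower"].std(ddof=1)) if trials > 1 else 0.0,
            "sd_upper": float(df["upper"].std(ddof=1)) if trials > 1 else 0.0,
            "n_ok": int(len(df)),
        }
        out[estimand] = s
    return out


def stability_table(records: pd.DataFrame) -> pd.DataFrame:
    """Sample SDs (ddof=1) of the interval endpoints per method."""
    if records["trial"].nunique() < 2:
        raise ValueError("need at least 2 trials for endpoint SDs")
    out = records.groupby("method").agg(
        sd_lower=("lower", lambda s: s.std(ddof=1)),
        sd_upper=("upper", lambda s: s.std(ddof=1)))
    return out
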