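"""Cross-validated models and minimum-performance library selection.

A *cross-validated model* is an ensemble of K identically parametrized
*siblings*, each trained on K-1 of K event-stratified folds.  Every training
sample receives exactly one out-of-fold prediction, produced by the sibling
that never saw it, so the full training data doubles as a validation set.
The library keeps only models whose average out-of-fold performance meets a
minimum threshold (absolute c_min for higher-is-better metrics, or a
relative within-(1+r)-of-best rule for lower-is-better metrics such as RMSE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .cohort import SurvivalCohort
from .exceptions import (
    FitFailureError,
    MetricUndefinedError,
    ValidationError,
)
from .learners import TIME_PREDICTION, LearnerSpec, SurvivalLearner
from .metrics import HIGHER_BETTER, LOWER_BETTER, METRIC_ORIENTATION, evaluate_metric

logger = logging.getLogger(__name__)


@dataclass
class FoldRecord:
    """Out-of-fold store for one fold: indices, predictions, ground truth."""

    test_index: np.ndarray
    predictions: np.ndarray
    times: np.ndarray
    events: np.ndarray


class CrossValidatedSurvivalModel(BaseEstimator):
    """K siblings of one learner spec plus their out-of-fold predictions.

    Fold assignment is event-stratified and driven entirely by
    ``(n_samples, events, k, random_state)``, so every spec fitted with the
    same seed on the same cohort sees identical partitions.

    Fitted attributes: ``siblings_`` (list of K fitted learners),
    ``oof_store_`` (list of :class:`FoldRecord`), ``oof_predictions_``
    (one prediction per training sample), ``failed_`` / ``error_``.
    """

    def __init__(self, family="cox_ridge", params=(), task=None, schema=None,
                 impute="median_mode", k=5, random_state=None):
        self.family = family
        self.params = params
        self.task = task
        self.schema = schema
        self.impute = impute
        self.k = k
        self.random_state = random_state

    @property
    def spec(self) -> LearnerSpec:
        return LearnerSpec(self.family, self.params, self.task)

    def fit(self, X: pd.DataFrame, y=None, *, time=None, event=None):
        if self.k < 2:
            raise ValidationError("k must be >= 2")
        if y is not None:
            time = np.asarray(y["time"], dtype=float)
            event = np.asarray(y["event"], dtype=bool)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        n = len(X)
        from sksurv.util import Surv

        folds = StratifiedKFold(
            n_splits=self.k, shuffle=True, random_state=self.random_state
        )
        self.siblings_ = []
        self.oof_store_ = []
        self.oof_predictions_ = np.full(n, np.nan)
        self.failed_ = False
        self.error_ = None
        self.mean_performance_ = None
        for train_idx, test_idx in folds.split(np.zeros(n), event.astype(int)):
            if event[train_idx].sum() < 2:
                self.failed_ = True
                self.error_ = "a training fold has fewer than 2 events"
                logger.warning("%s: %s", self.spec.label(), self.error_)
                return self
            sib = SurvivalLearner(
                family=self.family, params=self.params, task=self.task,
                schema=self.schema, impute=self.impute,
                random_state=self.random_state,
            )
            try:
                Xtr = X.iloc[train_idx] if isinstance(X, pd.DataFrame) else X[train_idx]
                Xte = X.iloc[test_idx] if isinstance(X, pd.DataFrame) else X[test_idx]
                sib.fit(Xtr, Surv.from_arrays(event[train_idx], time[train_idx]))
                pred = sib.predict(Xte)
            except (FitFailureError, ValidationError) as exc:
                self.failed_ = True
                self.error_ = str(exc)
                logger.warning("sibling fit failed for %s: %s", self.spec.label(), exc)
                return self
            self.siblings_.append(sib)
            self.oof_store_.append(
                FoldRecord(
                    test_index=np.asarray(test_idx),
                    predictions=pred,
                    times=time[test_idx],
                    events=event[test_idx],
                )
            )
            self.oof_predictions_[test_idx] = pred
        return self

    def oof_performance(self, metric: str = "cindex", pooled: bool = False) -> float:
        """Average out-of-fold performance c-bar (per-fold mean by default).

        ``pooled=True`` instead computes one metric over all out-of-fold
        predictions at once; the per-fold average is the default because the
        pruning stage consumes the *average cross-validation performance*.
        Folds where the metric is undefined are skipped with a warning.
        """
        if self.failed_ or not self.oof_store_:
            raise ValidationError("model failed to fit; no out-of-fold store")
        preds = {
            "rmse": lambda rec: rec.predictions,
        }.get(metric, lambda rec: self._as_risk(rec.predictions))
        if pooled:
            all_pred = np.concatenate([preds(r) for r in self.oof_store_])
            all_t = np.concatenate([r.times for r in self.oof_store_])
            all_e = np.concatenate([r.events for r in self.oof_store_])
            value = evaluate_metric(metric, all_t, all_e, all_pred)
        else:
            per_fold = []
            for i, rec in enumerate(self.oof_store_):
                try:
                    per_fold.append(
                        evaluate_metric(metric, rec.times, rec.events, preds(rec))
                    )
                except MetricUndefinedError as exc:
                    logger.warning(
                        "%s: fold %d skipped (%s)", self.spec.label(), i, exc
                    )
            if not per_fold:
                raise MetricUndefinedError(
                    f"{metric} undefined on every fold of {self.spec.label()}"
                )
            value = float(np.mean(per_fold))
        self.mean_performance_ = value
        return value

    def _as_risk(self, pred):
        return -pred if self.spec.task == TIME_PREDICTION else pred

    def predict(self, X) -> np.ndarray:
        """Elementwise mean of the K siblings' native predictions."""
        if self.failed_:
            raise ValidationError("model failed to fit")
        return np.mean([s.predict(X) for s in self.siblings_], axis=0)

    def predict_risk(self, X) -> np.ndarray:
        return self._as_risk(self.predict(X))


@dataclass
class ThresholdSpec:
    """Minimum-performance rule: absolute ``c_min`` (higher better) or keep
    within ``(1 + rel) * best`` (lower better, e.g. RMSE)."""

    c_min: float = None
    rel: float = None

    def __post_init__(self):
        if (self.c_min is None) == (self.rel is None):
            raise ValidationError("set exactly one of c_min (absolute) or rel (relative)")

    @property
    def orientation(self):
        return HIGHER_BETTER if self.c_min is not None else LOWER_BETTER

    def keep(self, performances: np.ndarray) -> np.ndarray:
        performances = np.asarray(performances, dtype=float)
        if self.c_min is not None:
            return performances >= self.c_min
        cutoff = (1.0 + self.rel) * np.nanmin(performances)
        return performances <= cutoff


@dataclass
class ModelLibrary:
    """Cross-validated models surviving minimum-performance selection."""

    members: list
    metric: str
    orientation: str
    threshold: ThresholdSpec = None
    performances: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0

    def __len__(self):
        return len(self.members)

    def n_siblings(self) -> int:
        return sum(len(m.siblings_) for m in self.members)


def fit_cross_validated(spec: LearnerSpec, cohort: SurvivalCohort, k: int = 5,
                        seed: int = None, impute="median_mode") -> CrossValidatedSurvivalModel:
    """Fit K siblings of one spec on a cohort (functional wrapper)."""
    model = CrossValidatedSurvivalModel(
        family=spec.family, params=spec.params, task=spec.task,
        schema=cohort.schema, impute=impute, k=k, random_state=seed,
    )
    return model.fit(cohort.frame, time=cohort.time, event=cohort.event)


def oof_performance(model: CrossValidatedSurvivalModel, metric: str = "cindex",
                    pooled: bool = False) -> float:
    return model.oof_performance(metric, pooled=pooled)


def predict_cv(model: CrossValidatedSurvivalModel, X) -> np.ndarray:
    return model.predict(X)


def select_models(models: list, threshold: ThresholdSpec, metric: str = "cindex") -> ModelLibrary:
    """Keep models whose stored mean performance satisfies the threshold.

    Survivor order is the input order.  An all-dropped result is returned as
    an explicitly flagged empty library, not an exception.
    """
    perfs = np.array(
        [m.mean_performance_ if m.mean_performance_ is not None
         else m.oof_performance(metric) for m in models],
        dtype=float,
    )
    keep = threshold.keep(perfs)
    members = [m for m, k in zip(models, keep) if k]
    if not members:
        logger.warning("selection produced an empty library (threshold %r)", threshold)
    return ModelLibrary(
        members=members,
        metric=metric,
        orientation=threshold.orientation,
        threshold=threshold,
        performances=perfs[keep],
    )


def build_library(
    specs: list,
    cohort: SurvivalCohort,
    k: int = 5,
    metric: str = "cindex",
    threshold: ThresholdSpec = None,
    seed: int = None,
    impute: str = "median_mode",
    pooled: bool = False,
):
    """Fit every spec as a cross-validated model, score, and select.

    Returns ``(library, report)`` where ``report`` is one row per spec with
    its mean performance and outcome (selected / dropped / failed).
    """
    if threshold is None:
        threshold = (ThresholdSpec(c_min=0.66) if METRIC_ORIENTATION[metric] == HIGHER_BETTER
                     else ThresholdSpec(rel=0.15))
    fitted, rows = [], []
    for spec in specs:
        model = fit_cross_validated(spec, cohort, k=k, seed=seed, impute=impute)
        if model.failed_:
            rows.append({"spec": spec.label(), "family": spec.family,
                         "performance": np.nan, "outcome": "failed",
                         "detail": model.error_})
            continue
        try:
            perf = model.oof_performance(metric, pooled=pooled)
        except MetricUndefinedError as exc:
            rows.append({"spec": spec.label(), "family": spec.family,
                         "performance": np.nan, "outcome": "failed",
                         "detail": str(exc)})
            continue
        fitted.append(model)
        rows.append({"spec": spec.label(), "family": spec.family,
                     "performance": perf, "outcome": "fitted", "detail": ""})
    library = select_models(fitted, threshold, metric=metric) if fitted else ModelLibrary(
        members=[], metric=metric, orientation=threshold.orientation, threshold=threshold
    )
    kept = {id(m) for m in library.members}
    for row, model in zip((r for r in rows if r["outcome"] == "fitted"), fitted):
        row["outcome"] = "selected" if id(model) in kept else "dropped"
    report = pd.DataFrame(rows)
    return library, report
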