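"""Uniform adapter over base survival learners, the clinical kernel,
hyper-parameter grid expansion and the repeated-split grid-search protocol.

The adapter's normative content is deliberately thin: it binds a fitted
encoder (or the clinical kernel) to an established estimator, enforces the
risk-orientation contract (higher score = higher risk for ranking families;
days for time-prediction families), and converts fit failures into structured
errors so that large library builds can skip and log rather than abort.
The estimators themselves come from scikit-survival.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedShuffleSplit

from .cohort import CONTINUOUS, NOMINAL, FeatureSchema, SurvivalCohort
from .encoding import CohortEncoder
from .exceptions import FitFailureError, ValidationError
from .metrics import HIGHER_BETTER, METRIC_ORIENTATION, evaluate_metric

logger = logging.getLogger(__name__)

RISK_RANKING = "risk_ranking"
TIME_PREDICTION = "time_prediction"

#: family name -> (native task, consumes a precomputed clinical kernel?)
FAMILIES = {
    "cox_ridge": (RISK_RANKING, False),
    "ssvm_linear": (RISK_RANKING, False),
    "ssvm_clinical_kernel": (RISK_RANKING, True),
    "gb_cox_tree": (RISK_RANKING, False),
    "gb_cox_componentwise": (RISK_RANKING, False),
    "rsf": (RISK_RANKING, False),
    "gb_aft_tree": (TIME_PREDICTION, False),
    "gb_aft_componentwise": (TIME_PREDICTION, False),
    "ssvm_hybrid_clinical": (TIME_PREDICTION, True),
}


@dataclass(frozen=True)
class LearnerSpec:
    """One library entry: a learner family with a hyper-parameter map."""

    family: str
    params: tuple = ()  # sorted (name, value) pairs; hashable
    task: str = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown learner family {self.family!r}")
        native_task, _ = FAMILIES[self.family]
        if isinstance(self.params, dict):
            object.__setattr__(self, "params", tuple(sorted(self.params.items())))
        task = self.task or native_task
        if task != native_task:
            raise ValidationError(
                f"family {self.family!r} is a {native_task} model, "
                f"incompatible with task {task!r}"
            )
        object.__setattr__(self, "task", task)

    @property
    def params_dict(self) -> dict:
        return dict(self.params)

    def label(self) -> str:
        ps = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({ps})"


def clinical_kernel(A: pd.DataFrame, B: pd.DataFrame, schema: FeatureSchema) -> np.ndarray:
    """Similarity kernel for mixed clinical features, averaged over features.

    Per feature: continuous -> (range - |a - b|) / range, clipped to [0, 1];
    nominal -> 1 if equal else 0; ordinal -> continuous formula on level
    ranks.  Values outside the schema range are clipped (similarity floor 0)
    with a logged warning.
    """
    n, m = len(A), len(B)
    total = np.zeros((n, m))
    for spec in schema:
        if spec.kind == CONTINUOUS:
            a = pd.to_numeric(A[spec.name], errors="coerce").to_numpy(dtype=float)
            b = pd.to_numeric(B[spec.name], errors="coerce").to_numpy(dtype=float)
            rng = spec.vmax - spec.vmin
            if np.nanmin(np.concatenate([a, b])) < spec.vmin or np.nanmax(
                np.concatenate([a, b])
            ) > spec.vmax:
                logger.warning(
                    "feature %r has values outside schema range [%g, %g]; "
                    "similarity clipped", spec.name, spec.vmin, spec.vmax,
                )
            diff = np.abs(a[:, None] - b[None, :])
            if rng > 0:
                sim = np.clip((rng - diff) / rng, 0.0, 1.0)
            else:
                sim = (diff == 0).astype(float)
        elif spec.kind == NOMINAL:
            a = A[spec.name].astype(str).to_numpy()
            b = B[spec.name].astype(str).to_numpy()
            sim = (a[:, None] == b[None, :]).astype(float)
        else:  # ordinal: ranks of levels, continuous formula
            order = {str(lv): i for i, lv in enumerate(spec.levels)}
            try:
                a = np.array([order[str(v)] for v in A[spec.name]], dtype=float)
                b = np.array([order[str(v)] for v in B[spec.name]], dtype=float)
            except KeyError as exc:
                raise ValidationError(
                    f"ordinal feature {spec.name!r}: unknown level {exc.args[0]!r}"
                ) from None
            rng = len(spec.levels) - 1
            if rng > 0:
                sim = np.clip((rng - np.abs(a[:, None] - b[None, :])) / rng, 0.0, 1.0)
            else:
                sim = np.ones((n, m))
        total += sim
    return total / len(schema)


def _build_estimator(spec: LearnerSpec, random_state):
    # imports kept local so the registry stays the single source of truth
    from sksurv.ensemble import (
        ComponentwiseGradientBoostingSurvivalAnalysis,
        GradientBoostingSurvivalAnalysis,
        RandomSurvivalForest,
    )
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.svm import FastKernelSurvivalSVM, FastSurvivalSVM

    p = spec.params_dict
    fam = spec.family
    if fam == "cox_ridge":
        return CoxPHSurvivalAnalysis(alpha=p.get("alpha", 1.0))
    if fam == "ssvm_linear":
        return FastSurvivalSVM(
            alpha=p.get("alpha", 1.0), max_iter=p.get("max_iter", 40),
            random_state=random_state,
        )
    if fam == "ssvm_clinical_kernel":
        return FastKernelSurvivalSVM(
            kernel="precomputed", alpha=p.get("alpha", 1.0), rank_ratio=1.0,
            max_iter=p.get("max_iter", 40), random_state=random_state,
        )
    if fam == "ssvm_hybrid_clinical":
        return FastKernelSurvivalSVM(
            kernel="precomputed", alpha=p.get("alpha", 1.0),
            rank_ratio=p.get("rank_ratio", 0.5), fit_intercept=True,
            max_iter=p.get("max_iter", 40), random_state=random_state,
        )
    if fam in ("gb_cox_tree", "gb_aft_tree"):
        return GradientBoostingSurvivalAnalysis(
            loss="coxph" if fam == "gb_cox_tree" else "ipcwls",
            learning_rate=p.get("learning_rate", 0.1),
            n_estimators=p.get("n_estimators", 100),
            max_depth=p.get("max_depth", 3),
            subsample=p.get("subsample", 1.0),
            max_features=p.get("max_features", None),
            min_samples_leaf=p.get("min_samples_leaf", 10),
            random_state=random_state,
        )
    if fam in ("gb_cox_componentwise", "gb_aft_componentwise"):
        return ComponentwiseGradientBoostingSurvivalAnalysis(
            loss="coxph" if fam == "gb_cox_componentwise" else "ipcwls",
            learning_rate=p.get("learning_rate", 0.1),
            n_estimators=p.get("n_estimators", 100),
        )
    if fam == "rsf":
        return RandomSurvivalForest(
            n_estimators=p.get("n_estimators", 100),
            max_features=p.get("max_features", "sqrt"),
            min_samples_leaf=p.get("min_samples_leaf", 10),
            random_state=random_state,
            n_jobs=1,
        )
    raise ValidationError(f"unknown learner family {fam!r}")


class SurvivalLearner(BaseEstimator):
    """Adapter wrapping one scikit-survival estimator behind a fixed contract.

    ``predict`` returns the family's native output — a risk score with
    *higher = higher risk* for ranking families, or predicted survival days
    for time-prediction families.  ``predict_risk`` always returns a
    higher-is-riskier score (time predictions are negated), so censored-data
    ranking metrics apply uniformly.
    """

    def __init__(self, family="cox_ridge", params=(), task=None, schema=None,
                 impute="median_mode", random_state=None):
        self.family = family
        self.params = params
        self.task = task
        self.schema = schema
        self.impute = impute
        self.random_state = random_state

    @property
    def spec(self) -> LearnerSpec:
        return LearnerSpec(self.family, self.params, self.task)

    def fit(self, X: pd.DataFrame, y):
        spec = self.spec
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        events = np.asarray(y["event"] if y.dtype.names else y, dtype=bool)
        if events.sum() < 2:
            raise ValidationError("need at least 2 observed events to fit")
        self.uses_kernel_ = FAMILIES[spec.family][1]
        try:
            self.encoder_ = CohortEncoder(schema=self.schema, impute=self.impute).fit(X)
            if self.uses_kernel_:
                self.train_frame_ = self.encoder_.impute_frame(X)
                design = clinical_kernel(
                    self.train_frame_, self.train_frame_, self.encoder_.schema_
                )
            else:
                design = self.encoder_.transform(X)
            est = _build_estimator(spec, self.random_state)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(design, y)
            pred = est.predict(design)
            if not np.all(np.isfinite(pred)):
                raise ValueError("non-finite training predictions")
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001 - structured failure by contract
            raise FitFailureError(spec, exc) from exc
        self.estimator_ = est
        return self

    def _design(self, X):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.encoder_.schema_.names)
        if self.uses_kernel_:
            return clinical_kernel(
                self.encoder_.impute_frame(X), self.train_frame_, self.encoder_.schema_
            )
        return self.encoder_.transform(X)

    def predict(self, X) -> np.ndarray:
        """Native-orientation prediction (risk score, or days for AFT-like)."""
        return np.asarray(self.estimator_.predict(self._design(X)), dtype=float)

    def predict_risk(self, X) -> np.ndarray:
        """Higher-is-riskier score regardless of family."""
        pred = self.predict(X)
        return -pred if self.spec.task == TIME_PREDICTION else pred


def fit_learner(spec: LearnerSpec, cohort: SurvivalCohort,
                impute="median_mode", random_state=None) -> SurvivalLearner:
    """Fit one library entry on a cohort."""
    model = SurvivalLearner(
        family=spec.family, params=spec.params, task=spec.task,
        schema=cohort.schema, impute=impute, random_state=random_state,
    )
    return model.fit(cohort.frame, cohort.to_surv())


def expand_grid(family: str, settings: dict, task: str = None) -> list[LearnerSpec]:
    """Cartesian product of hyper-parameter value lists, deterministic order."""
    if not settings:
        return [LearnerSpec(family, (), task)]
    names = list(settings)
    for name in names:
        if len(settings[name]) == 0:
            raise ValidationError(f"empty value list for hyper-parameter {name!r}")
    specs = []
    for combo in itertools.product(*(settings[n] for n in names)):
        specs.append(LearnerSpec(family, tuple(zip(names, combo)), task))
    return specs


def default_library_grids(task: str = RISK_RANKING) -> dict:
    """Default per-family hyper-parameter grids.

    Sized to the library composition used for the two prediction tasks:
    1,728 tree-boosting configurations, 36 componentwise-boosting, 24 random
    survival forests and 13 kernel SSVMs for risk ranking (1,801 total);
    1,728 + 36 + 78 = 1,842 for survival-time prediction.
    """
    tree_grid = {
        "learning_rate": [0.01, 0.05, 0.1, 0.25],
        "n_estimators": [100, 250, 500, 1000],
        "max_depth": [1, 2, 3, 4],
        "subsample": [0.5, 0.75, 1.0],
        "max_features": [0.25, 0.5, 1.0],
        "min_samples_leaf": [5, 10, 20],
    }
    comp_grid = {
        "learning_rate": [0.01, 0.025, 0.05, 0.1, 0.25, 0.5],
        "n_estimators": [100, 200, 300, 500, 750, 1000],
    }
    if task == RISK_RANKING:
        return {
            "gb_cox_tree": tree_grid,
            "gb_cox_componentwise": comp_grid,
            "rsf": {
                "n_estimators": [250, 500, 750, 1000],
                "max_features": ["sqrt", "log2", 0.5],
                "min_samples_leaf": [10, 20],
            },
            "ssvm_clinical_kernel": {"alpha": [float(2.0 ** k) for k in range(-6, 7)]},
        }
    if task == TIME_PREDICTION:
        return {
            "gb_aft_tree": tree_grid,
            "gb_aft_componentwise": comp_grid,
            "ssvm_hybrid_clinical": {
                "alpha": [float(2.0 ** k) for k in range(-6, 7)],
                "rank_ratio": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5],
            },
        }
    raise ValidationError(f"unknown task {task!r}")


def grid_search_fit(
    family: str,
    grid: list,
    cohort: SurvivalCohort,
    metric: str = "cindex",
    n_repeats: int = 10,
    train_fraction: float = 0.8,
    seed: int = 0,
    task: str = None,
    impute: str = "median_mode",
):
    """Repeated-random-split grid search, then refit on the full cohort.

    Each hyper-parameter map is scored on ``n_repeats`` event-stratified
    random splits (``train_fraction`` for training, the rest for testing) and
    the map with the best average score is refit on the complete data.
    Returns ``(fitted_learner, best_params, results)`` where ``results`` maps
    each candidate to its mean score (NaN when every split failed).
    """
    if isinstance(grid, dict):
        grid = expand_grid(family, grid, task).__iter__()
        grid = [s.params_dict for s in grid]
    if not grid:
        raise ValidationError("empty hyper-parameter grid")
    orientation = METRIC_ORIENTATION[metric]
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=1.0 - train_fraction, random_state=seed
    )
    splits = list(splitter.split(np.zeros(cohort.n_samples), cohort.event.astype(int)))

    results, failures = [], {}
    for params in grid:
        spec = LearnerSpec(family, tuple(sorted(params.items())), task)
        scores = []
        for tr, te in splits:
            try:
                model = fit_learner(spec, cohort.subset(tr), impute=impute,
                                    random_state=seed)
                test = cohort.subset(te)
                if metric == "rmse":
                    pred = model.predict(test.frame)
                else:
                    pred = model.predict_risk(test.frame)
                scores.append(
                    evaluate_metric(metric, test.time, test.event, pred,
                                    train_times=cohort.time[tr],
                                    train_events=cohort.event[tr])
                )
            except Exception as exc:  # noqa: BLE001 - skip-and-log protocol
                failures.setdefault(spec.label(), []).append(str(exc))
        mean = float(np.mean(scores)) if scores else float("nan")
        results.append((params, mean))
        logger.info("grid search %s: mean %s = %s", spec.label(), metric, mean)

    valid = [(p, s) for p, s in results if np.isfinite(s)]
    if not valid:
        raise FitFailureError(
            LearnerSpec(family, (), task),
            f"all candidate fits failed: {failures}",
        )
    key = (lambda ps: ps[1]) if orientation == HIGHER_BETTER else (lambda ps: -ps[1])
    best_params = max(valid, key=key)[0]
    best_spec = LearnerSpec(family, tuple(sorted(best_params.items())), task)
    fitted = fit_learner(best_spec, cohort, impute=impute, random_state=seed)
    return fitted, best_params, results
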