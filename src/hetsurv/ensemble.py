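"""Top-level heterogeneous survival ensemble estimator.

``fit`` builds a library of cross-validated models (K siblings per
hyper-parameter configuration), scores each by out-of-fold performance and
keeps those meeting the minimum-performance threshold; ``predict`` prunes the
library to the top-S members by combined accuracy + diversity on the test
features and aggregates their predictions.  The estimator follows sklearn
conventions (get_params/set_params, fitted attributes with a trailing
underscore) and composes with sklearn model-selection tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import SurvivalCohort
from .exceptions import EmptyLibraryError, ValidationError
from .learners import TIME_PREDICTION, LearnerSpec
from .metrics import HIGHER_BETTER, METRIC_ORIENTATION, concordance_index
from .pruning import PruningConfig, ensemble_predict
from .selection import ThresholdSpec, build_library


class HeterogeneousSurvivalEnsemble(BaseEstimator):
    """Heterogeneous ensemble of cross-validated survival models.

    Parameters
    ----------
    specs : list of LearnerSpec or (family, params) tuples
        The candidate library, one entry per hyper-parameter configuration.
    k : int
        Folds per cross-validated model (siblings per library member).
    metric : {"cindex", "iauc", "rmse"}
        Out-of-fold performance measure; fixes the orientation.
    c_min, rel_threshold :
        Minimum-performance rule; ``c_min`` (absolute, higher better,
        default 0.66) or ``rel_threshold`` (keep within (1+r)*best, lower
        better, default 0.15 for RMSE).
    tau_corr, correlation_method, top_fraction / ensemble_size, aggregation :
        Pruning-stage settings (defaults: 0.6, Pearson, top 5%, mean).
    diversity_basis : optional
        Defaults to risk-score correlation on the new data for ranking
        libraries and training residual correlation for time prediction.
    """

    def __init__(self, specs=None, k=5, metric="cindex", c_min=0.66,
                 rel_threshold=None, tau_corr=0.6, correlation_method="pearson",
                 top_fraction=0.05, ensemble_size=None, aggregation="mean",
                 diversity_basis=None, schema=None, impute="median_mode",
                 random_state=None):
        self.specs = specs
        self.k = k
        self.metric = metric
        self.c_min = c_min
        self.rel_threshold = rel_threshold
        self.tau_corr = tau_corr
        self.correlation_method = correlation_method
        self.top_fraction = top_fraction
        self.ensemble_size = ensemble_size
        self.aggregation = aggregation
        self.diversity_basis = diversity_basis
        self.schema = schema
        self.impute = impute
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _resolved_specs(self) -> list[LearnerSpec]:
        if not self.specs:
            raise ValidationError("specs must be a nonempty list")
        out = []
        for s in self.specs:
            if isinstance(s, LearnerSpec):
                out.append(s)
            else:
                family, params = s
                out.append(LearnerSpec(family, tuple(sorted(dict(params).items()))))
        tasks = {s.task for s in out}
        if len(tasks) > 1:
            raise ValidationError(f"mixed tasks in one library: {sorted(tasks)}")
        return out

    def _threshold(self) -> ThresholdSpec:
        if METRIC_ORIENTATION[self.metric] == HIGHER_BETTER:
            return ThresholdSpec(c_min=self.c_min)
        return ThresholdSpec(rel=0.15 if self.rel_threshold is None else self.rel_threshold)

    def _pruning_config(self) -> PruningConfig:
        specs = self._resolved_specs()
        basis = self.diversity_basis
        if basis is None:
            basis = ("residuals_on_training" if specs[0].task == TIME_PREDICTION
                     else "predictions_on_new_data")
        size = self.ensemble_size
        frac = self.top_fraction if size is None else None
        return PruningConfig(size=size, top_fraction=frac, tau_corr=self.tau_corr,
                             method=self.correlation_method,
                             diversity_basis=basis, aggregation=self.aggregation)

    # ------------------------------------------------------------------
    def fit(self, X, y=None, *, time=None, event=None):
        """Build and select the library on (X, time, event).

        ``X`` may be a feature DataFrame with ``time``/``event`` arrays, a
        structured scikit-survival ``y``, or a :class:`SurvivalCohort`.
        """
        if isinstance(X, SurvivalCohort):
            cohort = X
        else:
            if y is not None:
                time = np.asarray(y["time"], dtype=float)
                event = np.asarray(y["event"], dtype=bool)
            frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(
                np.asarray(X, dtype=float),
                columns=[f"x{i}" for i in range(np.asarray(X).shape[1])],
            )
            cohort = SurvivalCohort(frame=frame, time=time, event=event,
                                    schema=self.schema)
        specs = self._resolved_specs()
        self.task_ = specs[0].task
        self.library_, self.report_ = build_library(
            specs, cohort, k=self.k, metric=self.metric,
            threshold=self._threshold(), seed=self.random_state,
            impute=self.impute,
        )
        self.n_features_in_ = len(cohort.schema)
        return self

    def predict(self, X, return_trace: bool = False):
        """Dynamic pruning on X, then aggregation of member predictions."""
        if self.library_.is_empty:
            raise EmptyLibraryError("no model survived selection; cannot predict")
        frame = X.frame if isinstance(X, SurvivalCohort) else X
        return ensemble_predict(self.library_, frame, self._pruning_config(),
                                return_trace=return_trace)

    def predict_risk(self, X) -> np.ndarray:
        """Higher-is-riskier score (negated days for time-prediction tasks).

        Note rank_mean aggregation already emits risk-oriented ranks for
        ranking tasks; for time tasks higher mean rank = longer survival,
        hence the negation applies to both aggregations.
        """
        pred = self.predict(X)
        return -pred if self.task_ == TIME_PREDICTION else pred

    def prune_trace(self, X):
        """Return the :class:`PrunedEnsemble` audit trace for this test set."""
        _, trace = self.predict(X, return_trace=True)
        return trace

    def score(self, X, y=None, *, time=None, event=None) -> float:
        """Harrell's c-index of the ensemble risk score on (X, time, event)."""
        if isinstance(X, SurvivalCohort):
            time, event = X.time, X.event
        elif y is not None:
            time = np.asarray(y["time"], dtype=float)
            event = np.asarray(y["event"], dtype=bool)
        return concordance_index(time, event, self.predict_risk(X))
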