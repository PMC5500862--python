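"""Accuracy/diversity pruning and aggregation of ensemble predictions.

Each library member gets an accuracy score relative to the best member
(c-bar_i / c_max for higher-is-better metrics, min RMSE / RMSE_i for
lower-is-better) and a diversity score d_i = (|L| - count_i) / |L|, where
count_i is the number of *other* members whose prediction vector correlates
with member i at or above a threshold tau_corr.  The top-S members by
combined score (accuracy + diversity) form the pruned ensemble; when the
library is already no larger than S it is returned unchanged.

Because risk-score diversity needs no ground truth, pruning can be postponed
to prediction time and computed on the test features themselves — the
ensemble is then *dynamic*: a different test set may select different
members.  Aggregation is the plain member mean, or the mean of per-member
sample ranks, which puts arbitrarily scaled risk scores on a common scale
before averaging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .metrics import HIGHER_BETTER, LOWER_BETTER, correlation
from .selection import ModelLibrary


@dataclass(frozen=True)
class PruningConfig:
    """Settings of the pruning/aggregation stage.

    Exactly one of ``size`` (absolute S) and ``top_fraction`` must be set.
    ``diversity_basis`` chooses between correlating member predictions on the
    new data (survival risk scores; enables dynamic pruning) and correlating
    member residuals on the training data (time-prediction libraries).
    """

    size: int = None
    top_fraction: float = None
    tau_corr: float = 0.6
    method: str = "pearson"
    diversity_basis: str = "predictions_on_new_data"
    aggregation: str = "mean"

    def __post_init__(self):
        if (self.size is None) == (self.top_fraction is None):
            raise ValidationError("set exactly one of size / top_fraction")
        if self.top_fraction is not None and not (0 < self.top_fraction <= 1):
            raise ValidationError("top_fraction must be in (0, 1]")
        if not (-1.0 <= self.tau_corr <= 1.0):
            raise ValidationError("tau_corr must be within [-1, 1]")
        if self.method not in ("pearson", "kendall"):
            raise ValidationError(f"unknown correlation method {self.method!r}")
        if self.diversity_basis not in ("predictions_on_new_data", "residuals_on_training"):
            raise ValidationError(f"unknown diversity basis {self.diversity_basis!r}")
        if self.aggregation not in ("mean", "rank_mean"):
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")

    def resolve_size(self, library_size: int) -> int:
        if self.size is not None:
            return int(self.size)
        # round half down: 5% of 1801 -> 90, 5% of 1842 -> 92
        return max(1, math.ceil(self.top_fraction * library_size - 0.5))


@dataclass
class PrunedEnsemble:
    """Top-S members with their accuracy, diversity and combined scores."""

    member_indices: np.ndarray  # into the library, sorted by combined score
    accuracy: np.ndarray        # aligned with the *library*
    diversity: np.ndarray
    combined: np.ndarray
    c_max: float
    pruned: bool                # False when |L| <= S (bypass branch)

    def __len__(self):
        return len(self.member_indices)


def prediction_matrix(library: ModelLibrary, X) -> np.ndarray:
    """n_samples x n_members matrix of member predictions on X."""
    if len(X) == 0:
        raise ValidationError("X must be nonempty")
    cols = []
    for j, member in enumerate(library.members):
        try:
            cols.append(np.asarray(member.predict(X), dtype=float))
        except Exception as exc:
            raise ValidationError(
                f"prediction failed for member {j} ({member.spec.label()}): {exc}"
            ) from exc
    return np.column_stack(cols)


def diversity_scores(M: np.ndarray, tau_corr: float = 0.6,
                     method: str = "pearson") -> np.ndarray:
    """Per-member diversity d_i = (|L| - count_i) / |L|.

    ``count_i`` counts members j != i with correlation(col_i, col_j) >=
    tau_corr.  A constant column yields the no-correlation sentinel, which
    never reaches the threshold, so it looks maximally diverse rather than
    crashing.  d_i ranges over [1/|L|, 1]: even a member correlated with
    everything keeps 1/|L| because it is never counted against itself.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 1:
        raise ValidationError("need a 2-D matrix with at least one column")
    if M.shape[0] < 2:
        raise ValidationError("correlation needs at least two rows")
    L = M.shape[1]
    d = np.empty(L)
    corr = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            corr[i, j] = corr[j, i] = correlation(M[:, i], M[:, j], method)
    for i in range(L):
        with np.errstate(invalid="ignore"):
            count = int(np.nansum(corr[i] >= tau_corr))
        d[i] = (L - count) / L
    return d


def accuracy_scores(performances, orientation: str) -> np.ndarray:
    """Relative accuracy in (0, 1]: c-bar_i / c_max, or min(RMSE) / RMSE_i."""
    perf = np.asarray(performances, dtype=float)
    if perf.size == 0:
        raise ValidationError("empty performance vector")
    if np.any(perf <= 0):
        raise ValidationError("performances must be strictly positive")
    if orientation == HIGHER_BETTER:
        return perf / perf.max()
    if orientation == LOWER_BETTER:
        return perf.min() / perf
    raise ValidationError(f"unknown orientation {orientation!r}")


def prune_top_s(library: ModelLibrary, accuracy, diversity,
                size: int = None, top_fraction: float = None) -> PrunedEnsemble:
    """Select the top-S members by combined accuracy + diversity score.

    When the library is no larger than S, it is passed through unpruned in
    its input order.  Boundary ties are broken by higher accuracy, then by
    input order.
    """
    acc = np.asarray(accuracy, dtype=float)
    div = np.asarray(diversity, dtype=float)
    L = len(library)
    if not (len(acc) == len(div) == L):
        raise ValidationError("score vectors must align with the library")
    cfg_size = PruningConfig(size=size, top_fraction=top_fraction, tau_corr=0.0)
    s = cfg_size.resolve_size(L)
    combined = acc + div
    c_max = float(np.max(library.performances)) if len(library.performances) else float("nan")
    if L <= s:
        order = np.arange(L)
        return PrunedEnsemble(order, acc, div, combined, c_max, pruned=False)
    order = np.lexsort((np.arange(L), -acc, -combined))[:s]
    return PrunedEnsemble(np.asarray(order), acc, div, combined, c_max, pruned=True)


def _aggregate(P: np.ndarray, aggregation: str) -> np.ndarray:
    if aggregation == "mean":
        return P.mean(axis=1)
    if P.shape[0] < 2:
        raise ValidationError(
            "rank_mean aggregation needs at least two samples; "
            "ranking a single prediction is undefined"
        )
    ranks = np.column_stack([stats.rankdata(P[:, j]) for j in range(P.shape[1])])
    return ranks.mean(axis=1)


def training_residual_matrix(library: ModelLibrary) -> np.ndarray:
    """Out-of-fold residuals (predicted - observed days) over event samples,
    one column per member; diversity basis for time-prediction libraries."""
    cols = []
    for member in library.members:
        pred = np.concatenate([r.predictions for r in member.oof_store_])
        times = np.concatenate([r.times for r in member.oof_store_])
        events = np.concatenate([r.events for r in member.oof_store_])
        cols.append((pred - times)[events.astype(bool)])
    return np.column_stack(cols)


def ensemble_predict(library: ModelLibrary, X, config: PruningConfig,
                     performances=None, return_trace: bool = False):
    """Prune the library on the given data and aggregate member predictions.

    With ``diversity_basis='predictions_on_new_data'`` the correlation matrix
    is computed from the member predictions on ``X`` itself (the dynamic
    ensemble); with ``'residuals_on_training'`` it comes from the stored
    out-of-fold residuals.  Returns the aggregated prediction vector, plus
    the :class:`PrunedEnsemble` trace when ``return_trace`` is set.
    """
    if library.is_empty:
        raise ValidationError("cannot predict from an empty library")
    if config.aggregation == "rank_mean" and len(X) < 2:
        raise ValidationError(
            "rank_mean aggregation is undefined for a single sample; "
            "prediction must be performed for a set of samples"
        )
    perf = np.asarray(
        library.performances if performances is None else performances, dtype=float
    )
    P = prediction_matrix(library, X)
    if config.diversity_basis == "predictions_on_new_data":
        basis = P
    else:
        basis = training_residual_matrix(library)
    div = diversity_scores(basis, tau_corr=config.tau_corr, method=config.method)
    acc = accuracy_scores(perf, library.orientation)
    ensemble = prune_top_s(library, acc, div,
                           size=config.size, top_fraction=config.top_fraction)
    agg = _aggregate(P[:, ensemble.member_indices], config.aggregation)
    return (agg, ensemble) if return_trace else agg
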