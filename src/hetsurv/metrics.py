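"""Censored-data performance measures and correlation measures.

Implements Harrell's concordance index, the Kaplan–Meier estimate of the
censoring distribution, the IPCW cumulative/dynamic time-dependent AUC and
its integrated (grid-mean) form, events-only RMSE for survival-time
prediction, and Pearson/Kendall correlation with a defined sentinel for
constant vectors.  Undefined situations raise :class:`MetricUndefinedError`
instead of silently returning 0.5 or NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import MetricUndefinedError, ValidationError

#: Days per (mean Gregorian) month; used to convert the 6-monthly AUC grid.
DAYS_PER_MONTH = 30.4375

#: Default horizons for the integrated AUC: every 6 months up to 30 months.
DEFAULT_AUC_GRID = tuple(m * DAYS_PER_MONTH for m in (6, 12, 18, 24, 30))

#: Sentinel returned by :func:`correlation` when either vector is constant.
#: NaN compares False against any threshold, so in diversity counting a
#: constant predictor is treated as uncorrelated with everything.
NO_CORRELATION = float("nan")


def _as_arrays(*vecs):
    arrs = [np.asarray(v, dtype=float) for v in vecs]
    n = {len(a) for a in arrs}
    if len(n) != 1:
        raise ValidationError(f"length mismatch: {[len(a) for a in arrs]}")
    return arrs


def concordance_index(times, events, risks) -> float:
    """Harrell's c-index with tied risks counting one half.

    A pair (i, j) is comparable iff sample i died (event=1) strictly before
    time j; it is concordant when the earlier death carries the higher risk
    score.  Pairs tied on time are not comparable.  Invariant under strictly
    increasing transforms of the risks.
    """
    t, e, r = _as_arrays(times, events, risks)
    e = e.astype(bool)
    # comparable[i, j]: i is an observed event and t_i < t_j
    comparable = e[:, None] & (t[:, None] < t[None, :])
    n_comp = comparable.sum()
    if n_comp == 0:
        raise MetricUndefinedError("concordance undefined: no comparable pair")
    greater = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    score = (comparable & greater).sum() + 0.5 * (comparable & tied).sum()
    return float(score / n_comp)


@dataclass(frozen=True)
class StepSurvivalFunction:
    """Right-continuous step function S(t), starting at 1 before the first
    drop time; used for the Kaplan–Meier censoring distribution G-hat."""

    times: np.ndarray
    probs: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.probs, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("step times must be strictly increasing")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12) or np.any(np.diff(p) > 1e-12):
            raise ValidationError("step probabilities must be nonincreasing in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probs", p)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.probs[np.clip(idx, 0, None)], 1.0)
        return float(out) if out.ndim == 0 else out


def censoring_survival(times, events) -> StepSurvivalFunction:
    """Kaplan–Meier estimate of the censoring survival function G-hat.

    Censoring (event=0) is treated as the event of interest; observed deaths
    only shrink the risk set.  With no censoring observed, G-hat is the
    constant-1 function.
    """
    t, e = _as_arrays(times, events)
    cens = ~e.astype(bool)
    uniq = np.unique(t[cens]) if cens.any() else np.array([])
    if uniq.size == 0:
        return StepSurvivalFunction(times=np.array([np.inf]), probs=np.array([1.0]))
    probs, s = [], 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum(cens & (t == u))
        s *= 1.0 - d / at_risk
        probs.append(s)
    return StepSurvivalFunction(times=uniq, probs=np.array(probs))


def cumulative_dynamic_auc(
    train_times, train_events, test_times, test_events, risks, t: float
) -> float:
    """IPCW cumulative/dynamic AUC at horizon ``t``.

    Cases are test samples that died by ``t``; controls are samples still
    under observation past ``t``.  Cases are reweighted by 1/G-hat(T_i), with
    G-hat the censoring Kaplan–Meier estimated on the *training* data.  Tied
    risks count one half.  A required weight with G-hat = 0 — cases beyond
    the training follow-up — raises an explicit error rather than NaN.
    """
    tt, te, r = _as_arrays(test_times, test_events, risks)
    te = te.astype(bool)
    ghat = censoring_survival(train_times, train_events)
    cases = te & (tt <= t)
    controls = tt > t
    if not cases.any() or not controls.any():
        raise MetricUndefinedError(
            f"AUC({t:g}) undefined: {cases.sum()} cases, {controls.sum()} controls"
        )
    g = ghat(tt[cases])
    if np.any(g <= 0):
        raise MetricUndefinedError(
            f"AUC({t:g}) not computable: censoring survival estimate is zero "
            "at a case event time (horizon exceeds training follow-up)"
        )
    w = 1.0 / g
    rc, rk = r[cases], r[controls]
    wins = (rc[:, None] > rk[None, :]).sum(axis=1) + 0.5 * (rc[:, None] == rk[None, :]).sum(axis=1)
    return float((w * wins).sum() / (w.sum() * len(rk)))


def integrated_auc(
    train_times, train_events, test_times, test_events, risks, grid=DEFAULT_AUC_GRID
) -> float:
    """Unweighted mean of the cumulative/dynamic AUC over a horizon grid.

    The default grid is every 6 months up to 30 months, converted at
    30.4375 days per month.  Non-computable horizons propagate as errors.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be nonempty and strictly increasing")
    aucs = [
        cumulative_dynamic_auc(train_times, train_events, test_times, test_events, risks, t)
        for t in grid
    ]
    return float(np.mean(aucs))


def rmse_on_events(times, events, predicted_times) -> float:
    """Root mean squared error of predicted survival time, over observed
    deaths only (censored samples carry no usable time-of-death)."""
    t, e, p = _as_arrays(times, events, predicted_times)
    e = e.astype(bool)
    if not e.any():
        raise MetricUndefinedError("RMSE undefined: no observed events")
    return float(np.sqrt(np.mean((t[e] - p[e]) ** 2)))


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson's r or Kendall's tau-b; constant input yields the
    :data:`NO_CORRELATION` sentinel instead of NaN-by-accident."""
    xa, ya = _as_arrays(x, y)
    if len(xa) < 2:
        raise ValidationError("correlation needs at least two observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return NO_CORRELATION
    if method == "pearson":
        return float(np.corrcoef(xa, ya)[0, 1])
    if method == "kendall":
        tau = stats.kendalltau(xa, ya).statistic
        return NO_CORRELATION if np.isnan(tau) else float(tau)
    raise ValidationError(f"unknown correlation method {method!r}")


# metric registry used by selection / CLI -----------------------------------

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

METRIC_ORIENTATION = {
    "cindex": HIGHER_BETTER,
    "iauc": HIGHER_BETTER,
    "rmse": LOWER_BETTER,
}


def evaluate_metric(name, times, events, predictions, train_times=None, train_events=None):
    """Uniform entry point for the named metrics on one prediction vector.

    For ``cindex`` and ``iauc`` the predictions are risk scores (higher =
    riskier); for ``rmse`` they are predicted days of survival.
    """
    if name == "cindex":
        return concordance_index(times, events, predictions)
    if name == "iauc":
        tt = times if train_times is None else train_times
        te = events if train_events is None else train_events
        return integrated_auc(tt, te, times, events, predictions)
    if name == "rmse":
        return rmse_on_events(times, events, predictions)
    raise ValidationError(f"unknown metric {name!r}")
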