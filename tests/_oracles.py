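"""Independent brute-force oracles used to validate the metric
implementations.  Everything here is written from the definitions by
explicit enumeration and stays deliberately independent of hetsurv."""

import numpy as np


def cindex_by_enumeration(times, events, risks):
    """Harrell's c by explicit loop over all ordered pairs.

    Comparable: i an event, t_i < t_j.  Concordant: r_i > r_j; ties half.
    Returns None when no pair is comparable.
    """
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if events[i] and times[i] < times[j]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return None if den == 0 else num / den


def censoring_km_by_product(times, events, t_eval):
    """Product-limit estimate of P(censoring time > t) at one time point,
    treating censoring (event=0) as the event of interest."""
    times = np.asarray(times, float)
    cens = ~np.asarray(events, bool)
    s = 1.0
    for u in sorted(set(times[cens])):
        if u > t_eval:
            break
        at_risk = np.sum(times >= u)
        d = np.sum(cens & (times == u))
        s *= 1.0 - d / at_risk
    return s


def ipcw_auc_by_enumeration(train_times, train_events, test_times, test_events,
                            risks, horizon):
    """Weighted Mann-Whitney sum over (case, control) pairs, with case
    weights 1/G-hat(T_i) from the training censoring KM.  Returns None when
    undefined, "zero-weight" when a weight would divide by zero."""
    num = wsum = 0.0
    cases = [i for i in range(len(test_times))
             if test_events[i] and test_times[i] <= horizon]
    controls = [j for j in range(len(test_times)) if test_times[j] > horizon]
    if not cases or not controls:
        return None
    for i in cases:
        g = censoring_km_by_product(train_times, train_events, test_times[i])
        if g <= 0:
            return "zero-weight"
        w = 1.0 / g
        wsum += w
        for j in controls:
            if risks[i] > risks[j]:
                num += w
            elif risks[i] == risks[j]:
                num += 0.5 * w
    return num / (wsum * len(controls))


def kendall_tau_b_by_pairs(x, y):
    """Kendall's tau-b by explicit concordant/discordant pair counting."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return None if denom == 0 else (conc - disc) / denom
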