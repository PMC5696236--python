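"""Naive O(n^2) reference implementations of the product-limit estimator and
the two-group log-rank test, written with explicit per-subject loops and kept
deliberately independent of the package's vectorized code paths."""

import math


def naive_km(times, events):
    """Return (event_times, survival) as plain lists by direct per-time
    counting of risk sets and deaths."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    surv = []
    s = 1.0
    for et in event_times:
        at_risk = 0
        deaths = 0
        for t, e in pairs:
            if t >= et:
                at_risk += 1
            if t == et and e == 1:
                deaths += 1
        s = s * (1.0 - deaths / at_risk)
        surv.append(s)
    return event_times, surv


def naive_km_eval(times, events, t):
    ets, surv = naive_km(times, events)
    s = 1.0
    for et, sv in zip(ets, surv):
        if et <= t:
            s = sv
    return s


def naive_logrank(group, times, events):
    """Return (chi2, o_minus_e_group_true, variance) by explicit per-event
    O/E/V tabulation over subjects."""
    data = list(zip(group, times, events))
    event_times = sorted({t for _, t, e in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        n = sum(1 for _, t, _ in data if t >= et)
        n1 = sum(1 for g, t, _ in data if t >= et and g)
        d = sum(1 for _, t, e in data if t == et and e == 1)
        d1 = sum(1 for g, t, e in data if t == et and e == 1 and g)
        o_minus_e += d1 - d * (n1 / n)
        if n > 1:
            var += d * (n1 / n) * (1.0 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o_minus_e * o_minus_e) / var if var > 0 else 0.0
    return chi2, o_minus_e, var


def naive_rmst(times, events, tau):
    """Integrate the naive KM curve on [0, tau] by summing rectangles."""
    ets, surv = naive_km(times, events)
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for et, sv in zip(ets, surv):
        if et >= tau:
            break
        area += (et - prev_t) * prev_s
        prev_t, prev_s = et, sv
    area += (tau - prev_t) * prev_s
    return area
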