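"""Independent brute-force reference implementations of the evaluation
metrics, written as plain loops straight from the definitions. These are
deliberately slow and share no code with the package."""

from __future__ import annotations

import numpy as np


def bf_km_curve(times, events, grid):
    """Product-limit curve by direct counting at each grid point."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    event_times = sorted({t for t, d in zip(times, events) if d == 1})
    out = []
    for g in grid:
        s = 1.0
        for u in event_times:
            if u <= g:
                at_risk = sum(1 for t in times if t >= u)
                deaths = sum(1 for t, d in zip(times, events) if t == u and d == 1)
                s *= 1.0 - deaths / at_risk
        out.append(s)
    return np.asarray(out)


def bf_harrell(times, events, risks):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


def bf_censor_km_before(train_times, train_events, t):
    """G(t-) by direct product over censoring times strictly below t."""
    cens_times = sorted({u for u, d in zip(train_times, train_events) if d == 0})
    s = 1.0
    for u in cens_times:
        if u < t:
            at_risk = sum(1 for x in train_times if x >= u)
            c = sum(1 for x, d in zip(train_times, train_events) if x == u and d == 0)
            s *= 1.0 - c / at_risk
    return s


def bf_uno(train_times, train_events, times, events, risks, tau):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1 and times[i] < tau:
                g = bf_censor_km_before(train_times, train_events, times[i])
                if g <= 0:
                    continue
                w = 1.0 / g**2
                den += w
                if risks[i] > risks[j]:
                    num += w
                elif risks[i] == risks[j]:
                    num += 0.5 * w
    return num / den


def bf_curve_at(curve, grid, t):
    """Linear interpolation of one curve at time t."""
    if t <= grid[0]:
        return curve[0]
    if t >= grid[-1]:
        return curve[-1]
    j = int(np.searchsorted(grid, t, side="right"))
    frac = (t - grid[j - 1]) / (grid[j] - grid[j - 1])
    return curve[j - 1] * (1 - frac) + curve[j] * frac


def bf_censor_km_at(train_times, train_events, t):
    """G(t), right-continuous."""
    cens_times = sorted({u for u, d in zip(train_times, train_events) if d == 0})
    s = 1.0
    for u in cens_times:
        if u <= t:
            at_risk = sum(1 for x in train_times if x >= u)
            c = sum(1 for x, d in zip(train_times, train_events) if x == u and d == 0)
            s *= 1.0 - c / at_risk
    return s


def bf_brier(curves, grid, times, events, train_times, train_events, at_time):
    n = len(times)
    total = 0.0
    g_t = bf_censor_km_at(train_times, train_events, at_time)
    for i in range(n):
        s = bf_curve_at(curves[i], grid, at_time)
        if times[i] <= at_time and events[i] == 1:
            g = bf_censor_km_before(train_times, train_events, times[i])
            if g > 0:
                total += s**2 / g
        elif times[i] > at_time:
            if g_t > 0:
                total += (1.0 - s) ** 2 / g_t
    return total / n


def bf_ibs(curves, grid, times, events, train_times, train_events, eval_grid):
    bs = [
        bf_brier(curves, grid, times, events, train_times, train_events, t)
        for t in eval_grid
    ]
    total = 0.0
    for a, b, ta, tb in zip(bs[:-1], bs[1:], eval_grid[:-1], eval_grid[1:]):
        total += 0.5 * (a + b) * (tb - ta)
    return total / (eval_grid[-1] - eval_grid[0])


def bf_margin_time(train_times, train_events, c):
    """c + integral of the KM tail (forced to zero at the last event time)
    divided by S(c), via direct step enumeration."""
    event_times = sorted({t for t, d in zip(train_times, train_events) if d == 1})

    def km(t):
        s = 1.0
        for u in event_times:
            if u <= t:
                at_risk = sum(1 for x in train_times if x >= u)
                deaths = sum(1 for x, d in zip(train_times, train_events) if x == u and d == 1)
                s *= 1.0 - deaths / at_risk
        return s

    s_c = km(c)
    if s_c <= 0:
        return float(c)
    knots = [c] + [u for u in event_times if u > c]
    integral = 0.0
    for a, b in zip(knots[:-1], knots[1:]):
        integral += (b - a) * km(a)
    return c + integral / s_c


def bf_margin_mae(pred, times, events, train_times, train_events):
    total = 0.0
    for p, t, d in zip(pred, times, events):
        target = t if d == 1 else bf_margin_time(train_times, train_events, t)
        total += abs(p - target)
    return total / len(times)


def bf_dcal_masses(probs, events, bins=10):
    mass = np.zeros(bins)
    width = 1.0 / bins
    for p, d in zip(probs, events):
        if d == 1:
            mass[min(int(p * bins), bins - 1)] += 1.0
        else:
            if p <= 0:
                mass[0] += 1.0
                continue
            j = min(int(p * bins), bins - 1)
            for b in range(j):
                mass[b] += width / p
            mass[j] += (p - j * width) / p
    return mass


def bf_dcal_statistic(probs, events, bins=10):
    mass = bf_dcal_masses(probs, events, bins)
    n = len(probs)
    exp = n / bins
    return float(((mass - exp) ** 2 / exp).sum())
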