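"""Censoring-aware evaluation of individual survival distributions.

All operations return natural-scale values (concordance and IBS in
[0, 1], margin MAE in days); any x100 presentation happens in the report
layer only. Risk scores are uniformly the negative median survival time,
so a higher score means an earlier predicted event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import HORIZON
from .nonparametric import KaplanMeier, censoring_km


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def harrell_ci(times, indicators, risks) -> float:
    """Harrell's concordance: fraction of comparable pairs ranked correctly.

    A pair (i, j) is comparable when t_i < t_j and patient i experienced
    the event; it is concordant when the earlier patient carries the
    higher risk score. Tied risks earn half credit.
    """
    t = np.asarray(times, float)
    d = np.asarray(indicators, int)
    r = np.asarray(risks, float)
    if not (len(t) == len(d) == len(r)):
        raise ValueError("times, indicators and risks must have equal length")
    comp = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comp = comp.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = (comp & (r[:, None] > r[None, :])).sum()
    ties = (comp & (r[:, None] == r[None, :])).sum()
    return float((conc + 0.5 * ties) / n_comp)


def uno_ci(
    train_times, train_indicators, times, indicators, risks, tau: float = HORIZON
) -> float:
    """Uno's IPCW concordance, weighting each comparable pair by
    1 / G(t_i-)^2 with G the training censoring-survival curve; pairs with
    t_i >= tau or G(t_i-) = 0 are excluded."""
    t = np.asarray(times, float)
    d = np.asarray(indicators, int)
    r = np.asarray(risks, float)
    G = censoring_km(np.asarray(train_times, float), np.asarray(train_indicators, int))
    g = np.asarray(G.survival_before(t), float)
    with np.errstate(divide="ignore"):
        w = np.where(g > 0, 1.0 / g**2, 0.0)  # zero weight = excluded pair
    comp = (t[:, None] < t[None, :]) & (d[:, None] == 1) & (t[:, None] < tau)
    wpair = comp * w[:, None]
    denom = wpair.sum()
    if denom == 0:
        raise ValueError("no comparable pairs below tau")
    conc = (wpair * (r[:, None] > r[None, :])).sum()
    ties = (wpair * (r[:, None] == r[None, :])).sum()
    return float((conc + 0.5 * ties) / denom)


# ---------------------------------------------------------------------------
# Brier score
# ---------------------------------------------------------------------------

def _curves_at(curves: np.ndarray, curve_grid: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Linear interpolation of (n, T) curves at per-evaluation times t (m,)
    -> (n, m)."""
    idx = np.clip(np.searchsorted(curve_grid, t, side="right"), 1, len(curve_grid) - 1)
    t0, t1 = curve_grid[idx - 1], curve_grid[idx]
    frac = np.where(t1 > t0, (t - t0) / (t1 - t0), 0.0)
    return curves[:, idx - 1] * (1 - frac) + curves[:, idx] * frac


def curves_at_own_times(curves: np.ndarray, curve_grid: np.ndarray, t: np.ndarray) -> np.ndarray:
    """S_i(t_i): each patient's own curve at their own observed time."""
    curves = np.asarray(curves, float)
    grid = np.asarray(curve_grid, float)
    idx = np.clip(np.searchsorted(grid, t, side="right"), 1, len(grid) - 1)
    t0, t1 = grid[idx - 1], grid[idx]
    frac = np.where(t1 > t0, (t - t0) / (t1 - t0), 0.0)
    rows = np.arange(len(t))
    return curves[rows, idx - 1] * (1 - frac) + curves[rows, idx] * frac


def brier_score(
    curves, curve_grid, times, indicators, censor_km_est: KaplanMeier, at_time: float
) -> float:
    """IPCW Brier score at one time point.

    Patients with an event by ``at_time`` contribute their squared
    predicted survival weighted by 1/G(t_i-); patients still event-free
    contribute (1 - S)^2 weighted by 1/G(at_time); patients censored
    before ``at_time`` contribute nothing.
    """
    t = np.asarray(times, float)
    d = np.asarray(indicators, int)
    s_at = _curves_at(np.asarray(curves, float), np.asarray(curve_grid, float),
                      np.asarray([at_time], float))[:, 0]
    g_ti = np.asarray(censor_km_est.survival_before(t), float)
    g_t = float(censor_km_est.survival_at(at_time))
    had_event = (t <= at_time) & (d == 1)
    event_free = t > at_time
    contrib = np.zeros_like(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib[had_event] = (s_at[had_event] ** 2) / g_ti[had_event]
        if g_t > 0:
            contrib[event_free] = ((1.0 - s_at[event_free]) ** 2) / g_t
    contrib[~np.isfinite(contrib)] = 0.0
    return float(contrib.sum() / len(t))


def integrated_brier_score(
    curves, curve_grid, times, indicators, censor_km_est: KaplanMeier,
    eval_grid: np.ndarray | None = None,
) -> float:
    """Trapezoidal average of the IPCW Brier score over an evaluation grid
    (default: 100 equally spaced points on (0, Tmax])."""
    if eval_grid is None:
        eval_grid = np.linspace(HORIZON / 100.0, HORIZON, 100)
    eval_grid = np.asarray(eval_grid, float)
    if eval_grid.size == 0:
        raise ValueError("empty evaluation grid")
    bs = np.array([
        brier_score(curves, curve_grid, times, indicators, censor_km_est, t)
        for t in eval_grid
    ])
    if eval_grid.size == 1:
        return float(bs[0])
    return float(np.trapezoid(bs, eval_grid) / (eval_grid[-1] - eval_grid[0]))


# ---------------------------------------------------------------------------
# margin MAE
# ---------------------------------------------------------------------------

def margin_mae(pred_times, times, indicators, train_km: KaplanMeier) -> float:
    """Mean absolute error of predicted event times with censored patients
    replaced by their KM "best-guess" margin time e(c) = c + int_c S / S(c)."""
    p = np.asarray(pred_times, float)
    t = np.asarray(times, float)
    d = np.asarray(indicators, int)
    target = t.copy()
    cen = d == 0
    if cen.any():
        target[cen] = train_km.margin_times(t[cen])
    return float(np.abs(p - target).mean())


# ---------------------------------------------------------------------------
# D-calibration
# ---------------------------------------------------------------------------

@dataclass
class DCalHistogram:
    bin_edges: np.ndarray
    observed: np.ndarray  # per-bin mass fractions, sum to 1
    statistic: float
    p_value: float
    passed: bool


def d_calibration(
    surv_probs_at_obs, indicators, bins: int = 10, alpha: float = 0.05
) -> DCalHistogram:
    """Pearson chi-squared uniformity test of S_i(t_i) over probability deciles.

    Uncensored patients put unit mass in the decile containing
    p_i = S_i(t_i). A censored patient with p = S_i(c_i) spreads unit mass
    uniformly over [0, p]: each fully covered decile receives 0.1/p and
    the decile containing p its covered fraction / p (all mass to the
    lowest decile when p = 0). The model passes when the test does not
    reject uniformity at ``alpha``.
    """
    p = np.asarray(surv_probs_at_obs, float)
    d = np.asarray(indicators, int)
    if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
        raise ValueError("survival probabilities must lie in [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, bins + 1)
    width = 1.0 / bins
    mass = np.zeros(bins)
    for pi, di in zip(p, d):
        if di == 1:
            mass[min(int(pi * bins), bins - 1)] += 1.0
        else:
            if pi <= 0.0:
                mass[0] += 1.0
                continue
            j = min(int(pi * bins), bins - 1)
            mass[:j] += width / pi
            mass[j] += (pi - edges[j]) / pi
    n = len(p)
    expected = np.full(bins, n / bins)
    statistic = float(((mass - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(statistic, df=bins - 1))
    return DCalHistogram(
        bin_edges=edges,
        observed=mass / n,
        statistic=statistic,
        p_value=p_value,
        passed=p_value > alpha,
    )


# ---------------------------------------------------------------------------
# one-call evaluation for a single event
# ---------------------------------------------------------------------------

def evaluate_single_event(
    curves: np.ndarray,
    curve_grid: np.ndarray,
    test_times: np.ndarray,
    test_indicators: np.ndarray,
    train_times: np.ndarray,
    train_indicators: np.ndarray,
    horizon: int = HORIZON,
) -> dict:
    """All five metrics for one model x event on a test split."""
    from .models.base import median_survival_time

    med = median_survival_time(curves, curve_grid, horizon)
    risks = -med
    train_km = KaplanMeier.fit(train_times, train_indicators)
    cens_km = censoring_km(train_times, train_indicators)
    p_obs = curves_at_own_times(curves, curve_grid, np.asarray(test_times, float))
    dcal = d_calibration(p_obs, test_indicators)
    return {
        "harrell_ci": harrell_ci(test_times, test_indicators, risks),
        "uno_ci": uno_ci(train_times, train_indicators, test_times, test_indicators, risks),
        "ibs": integrated_brier_score(
            curves, curve_grid, test_times, test_indicators, cens_km
        ),
        "mmae": margin_mae(med, test_times, test_indicators, train_km),
        "dcal_pass": bool(dcal.passed),
        "dcal_pvalue": dcal.p_value,
    }
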