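"""Multi-task logistic regression (MTLR) for individual survival curves.

The horizon is discretized into quantile-spaced intervals. Each interval
carries a linear score phi_j(x) = theta_j . x + b_j; the probability that
the event falls in interval j is proportional to exp(sum_{l >= j} phi_l),
with an extra "beyond the horizon" outcome of score 0. Censored patients
contribute the marginal likelihood summed over all intervals compatible
with their censoring time. An L2 penalty on the weight matrix regularizes
the fit. No proportional-hazards constraint is imposed.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from ..config import DEFAULTS, HORIZON
from ..containers import SurvivalDataset, default_time_grid
from .base import SurvivalModel

log = logging.getLogger(__name__)


def make_bin_edges(times: np.ndarray, n_bins: int, horizon: int = HORIZON) -> np.ndarray:
    """Quantile-spaced interior edges; duplicate quantiles (empty bins) merge."""
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.quantile(np.asarray(times, float), qs)
    edges = np.unique(edges)
    edges = edges[(edges > 0) & (edges < horizon)]
    if edges.size < n_bins - 1:
        log.info("merged %d empty time bins", n_bins - 1 - edges.size)
    return np.concatenate((edges, [float(horizon)]))  # upper boundaries tau_1..tau_m


class MTLRModel(SurvivalModel):
    model_kind = "mtlr"

    def __init__(self, event_index: int = 0, n_bins: int = DEFAULTS.mtlr_bins,
                 l2: float = DEFAULTS.mtlr_l2, horizon: int = HORIZON):
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        self.event_index = event_index
        self.n_bins = n_bins
        self.l2 = l2
        self.horizon = horizon
        self.edges_: np.ndarray | None = None  # upper boundaries, length m
        self.theta_: np.ndarray | None = None  # (m, d)
        self.bias_: np.ndarray | None = None   # (m,)

    # -- likelihood ---------------------------------------------------------

    def _scores(self, X, theta, bias):
        phi = X @ theta.T + bias           # (n, m)
        G = np.cumsum(phi[:, ::-1], axis=1)[:, ::-1]  # G_j = sum_{l>=j} phi_l
        return np.concatenate((G, np.zeros((len(X), 1))), axis=1)  # outcome m+1: beyond

    def _nll_grad(self, params, X, bin_idx, delta):
        n, d = X.shape
        m = len(self.edges_)
        theta = params[: m * d].reshape(m, d)
        bias = params[m * d :]
        G = self._scores(X, theta, bias)   # (n, m+1)
        logZ = logsumexp(G, axis=1)
        P = np.exp(G - logZ[:, None])      # (n, m+1)
        # target distribution Q over outcomes: point mass (uncensored) or
        # renormalized over compatible outcomes {bin(c)..m, beyond}
        Q = np.zeros_like(G)
        unc = delta == 1
        Q[unc, bin_idx[unc]] = 1.0
        cen = ~unc
        if cen.any():
            mask = np.arange(m + 1)[None, :] >= bin_idx[cen][:, None]
            Gc = np.where(mask, G[cen], -np.inf)
            lZc = logsumexp(Gc, axis=1)
            Q[cen] = np.where(mask, np.exp(Gc - lZc[:, None]), 0.0)
            ll_cen = lZc - logZ[cen]
        nll = -(G[unc, bin_idx[unc]] - logZ[unc]).sum()
        if cen.any():
            nll -= ll_cen.sum()
        # d nll / d phi_j = cum_{l<=j} P - cum_{l<=j} Q  (outcomes 1..m only)
        diff = np.cumsum(P - Q, axis=1)[:, :m]   # (n, m)
        grad_theta = diff.T @ X + self.l2 * theta
        grad_bias = diff.sum(axis=0)
        nll += 0.5 * self.l2 * (theta**2).sum()
        return nll, np.concatenate((grad_theta.ravel(), grad_bias))

    # -- fitting ------------------------------------------------------------

    def fit(self, train: SurvivalDataset, validation=None) -> "MTLRModel":
        X = np.asarray(train.X, dtype=float)
        times = train.times[:, self.event_index].astype(float)
        delta = train.events[:, self.event_index]
        self.edges_ = make_bin_edges(times, self.n_bins, self.horizon)
        m, d = len(self.edges_), X.shape[1]
        # outcome index of a time: first interval whose upper boundary covers it
        bin_idx = np.searchsorted(self.edges_, times, side="left")
        bin_idx = np.clip(bin_idx, 0, m)  # times at the horizon fall in the last bin
        x0 = np.zeros(m * d + m)
        res = minimize(
            self._nll_grad, x0, args=(X, bin_idx, delta), jac=True,
            method="L-BFGS-B", options={"maxiter": 500},
        )
        self.theta_ = res.x[: m * d].reshape(m, d)
        self.bias_ = res.x[m * d :]
        return self

    def predict_survival(self, X: np.ndarray, time_grid=None) -> np.ndarray:
        if self.theta_ is None:
            raise RuntimeError("model not fitted")
        X = np.asarray(X, dtype=float)
        grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
        G = self._scores(X, self.theta_, self.bias_)
        logZ = logsumexp(G, axis=1)
        P = np.exp(G - logZ[:, None])
        # survival at upper boundary tau_j = P(outcome > j)
        surv_at_edges = 1.0 - np.cumsum(P[:, :-1], axis=1)
        knots = np.concatenate(([0.0], self.edges_))
        vals = np.concatenate((np.ones((len(X), 1)), surv_at_edges), axis=1)
        out = np.empty((len(X), len(grid)))
        for i in range(len(X)):
            out[i] = np.interp(grid, knots, vals[i], right=vals[i, -1])
        return np.clip(out, 0.0, 1.0)
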