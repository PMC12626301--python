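"""Deep Cox model: a one-hidden-layer MLP risk score trained on the Cox
partial likelihood, with a Breslow baseline hazard on the training risks.

The network is deliberately small (single hidden layer, 32 tanh units,
linear output) and trained full-batch with Adam; early stopping monitors
the validation partial likelihood with a fixed patience. Proportional
hazards still hold — only the risk score is nonlinear in the covariates.
"""

from __future__ import annotations

import numpy as np

from ..config import DEFAULTS
from ..containers import SurvivalDataset, default_time_grid
from .base import SurvivalModel
from .coxph import breslow_baseline, cumhaz_on_grid


def _cox_nll_and_grad_eta(eta, times, events):
    """Efron-tie negative partial log-likelihood and its gradient in eta.

    The gradient splits into a risk-set term, shared with all patients at
    risk (accumulated as suffix sums of sum_l 1/E0_l per event block), and
    a tied-event correction applied only to the block's event cases.
    """
    order = np.argsort(-times, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    e, t, d = eta[order], times[order], events[order]
    shift = e.max()
    w = np.exp(e - shift)
    cumw = np.cumsum(w)
    n = len(t)
    nll = 0.0
    coef = np.zeros(n)        # suffix-summed risk-set coefficient
    extra = np.zeros(n)       # per-event-case Efron correction
    i = 0
    n_ev = 0
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        dblock = d[i : j + 1] == 1
        m = int(dblock.sum())
        if m > 0:
            S0 = cumw[j]
            D0 = w[i : j + 1][dblock].sum()
            f = np.arange(m) / m
            E0 = S0 - f * D0
            nll -= (e[i : j + 1][dblock]).sum() - (np.log(E0).sum() + m * shift)
            coef[j] += np.sum(1.0 / E0)
            # event cases additionally get -w_i * sum_l(f_l / E0_l)
            extra_idx = np.flatnonzero(dblock) + i
            extra[extra_idx] -= np.sum(f / E0)
            n_ev += m
        i = j + 1
    if n_ev == 0:
        raise ValueError("no events in sample")
    tail = np.cumsum(coef[::-1])[::-1]
    grad_sorted = w * (tail + extra) - d
    return nll, grad_sorted[inv]


class DeepCoxModel(SurvivalModel):
    model_kind = "deepcox"

    def __init__(self, event_index: int = 0, hidden: int = DEFAULTS.hidden,
                 patience: int = DEFAULTS.patience, max_epochs: int = DEFAULTS.max_epochs,
                 learning_rate: float = DEFAULTS.learning_rate, seed: int = 0):
        self.event_index = event_index
        self.hidden = hidden
        self.patience = patience
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.params_: dict | None = None
        self.baseline_times_: np.ndarray | None = None
        self.baseline_cumhaz_: np.ndarray | None = None
        self.epochs_run_: int = 0
        self.early_stopped_: bool = False

    def _risk(self, X, params):
        h = np.tanh(X @ params["W1"] + params["b1"])
        return h @ params["w2"], h

    def fit(self, train: SurvivalDataset, validation: SurvivalDataset | None = None) -> "DeepCoxModel":
        X = np.asarray(train.X, dtype=float)
        t = train.times[:, self.event_index].astype(float)
        d = train.events[:, self.event_index]
        rng = np.random.default_rng(self.seed)
        nin = X.shape[1]
        params = {
            "W1": rng.normal(0, 1 / np.sqrt(nin), (nin, self.hidden)),
            "b1": np.zeros(self.hidden),
            "w2": rng.normal(0, 1 / np.sqrt(self.hidden), self.hidden),
        }
        mom = {k: np.zeros_like(v) for k, v in params.items()}
        vel = {k: np.zeros_like(v) for k, v in params.items()}
        best = {k: v.copy() for k, v in params.items()}
        best_val = np.inf
        best_epoch = 0
        stale = 0
        step = 0
        for epoch in range(1, self.max_epochs + 1):
            eta, h = self._risk(X, params)
            nll, g_eta = _cox_nll_and_grad_eta(eta, t, d)
            if not np.isfinite(nll):
                raise RuntimeError(
                    f"diverged (non-finite loss) at epoch {epoch}, seed {self.seed}"
                )
            g_eta = g_eta / len(t)
            grads = {
                "w2": h.T @ g_eta,
                "b1": None,
                "W1": None,
            }
            dh = np.outer(g_eta, params["w2"]) * (1 - h**2)
            grads["W1"] = X.T @ dh
            grads["b1"] = dh.sum(axis=0)
            step += 1
            for k in params:
                mom[k] = 0.9 * mom[k] + 0.1 * grads[k]
                vel[k] = 0.999 * vel[k] + 0.001 * grads[k] ** 2
                mhat = mom[k] / (1 - 0.9**step)
                vhat = vel[k] / (1 - 0.999**step)
                params[k] -= self.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
            self.epochs_run_ = epoch
            if validation is not None and validation.n > 0:
                veta, _ = self._risk(np.asarray(validation.X, float), params)
                vt = validation.times[:, self.event_index].astype(float)
                vd = validation.events[:, self.event_index]
                try:
                    vloss, _ = _cox_nll_and_grad_eta(veta, vt, vd)
                except ValueError:
                    vloss = np.inf
                if vloss < best_val - 1e-9:
                    best_val = vloss
                    best = {k: v.copy() for k, v in params.items()}
                    best_epoch = epoch
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        self.early_stopped_ = True
                        break
        if validation is not None and best_val < np.inf:
            params = best
            self.best_epoch_ = best_epoch
        self.params_ = params
        eta, _ = self._risk(X, params)
        self.baseline_times_, self.baseline_cumhaz_ = breslow_baseline(eta, t, d)
        return self

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        eta, _ = self._risk(np.asarray(X, float), self.params_)
        return eta

    def predict_survival(self, X: np.ndarray, time_grid=None) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("model not fitted")
        grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
        H0 = cumhaz_on_grid(self.baseline_times_, self.baseline_cumhaz_, grid)
        eta = self.predict_risk(X)
        return np.exp(-np.outer(np.exp(eta), H0))
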