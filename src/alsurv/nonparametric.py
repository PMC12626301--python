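"""Product-limit estimation and margin ("best-guess") event times.

The Kaplan-Meier estimator is implemented directly from its definition
because it is load-bearing in four places — the covariate-free baseline
model, the censoring-distribution weights of Uno's concordance and the
IPCW Brier score, and the margin time that replaces a censored patient's
unknown event time. An independent implementation (lifelines) is used as
a cross-check in the test suite, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KaplanMeier:
    """Product-limit survival curve fitted on right-censored data.

    ``S(t)`` is a right-continuous step function with ``S(0) = 1``; steps
    occur only at observed event times.
    """

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray     # S at those times (post-step values)

    @classmethod
    def fit(cls, times: np.ndarray, events: np.ndarray) -> "KaplanMeier":
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.size == 0:
            raise ValueError("cannot fit Kaplan-Meier on an empty sample")
        if np.any(times <= 0):
            raise ValueError("times must be strictly positive")
        order = np.argsort(times, kind="stable")
        t, d = times[order], events[order]
        uniq, start = np.unique(t, return_index=True)
        n = t.size
        at_risk = n - start  # risk set just before each distinct time
        n_events = np.add.reduceat(d, start)
        keep = n_events > 0
        factors = 1.0 - n_events[keep] / at_risk[keep]
        surv = np.cumprod(factors)
        return cls(event_times=uniq[keep], survival=surv)

    def survival_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """S(t), right-continuous (value after any step at t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def survival_before(self, t: np.ndarray | float) -> np.ndarray | float:
        """Left limit S(t-) (value just before t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="left")
        s = np.concatenate(([1.0], self.survival))
        return s[idx]

    def curve_on_grid(self, grid: np.ndarray) -> np.ndarray:
        return np.asarray(self.survival_at(grid), dtype=float)

    def margin_time(self, c: float) -> float:
        """Best-guess event time for a patient censored at ``c``.

        Conditional expected event time given survival past ``c``::

            e(c) = c + \\int_c^inf S(u) du / S(c)

        with the estimated curve forced to 0 beyond its last event time
        (so the integral is finite even when the last observation is
        censored). If ``S(c) = 0`` there is no mass beyond ``c`` and the
        margin time is ``c`` itself.
        """
        return float(self.margin_times(np.asarray([c]))[0])

    def margin_times(self, c: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`margin_time` for an array of censoring times."""
        c = np.asarray(c, dtype=float)
        ts = self.event_times
        s = np.concatenate(([1.0], self.survival))  # heights on [0,t1), [t1,t2), ...
        edges = np.concatenate(([0.0], ts))
        widths = np.diff(edges)
        seg = widths * s[:-1]
        # tail[i] = integral of S from edges[i] to the last event time
        tail = np.concatenate((np.cumsum(seg[::-1])[::-1], [0.0]))
        idx = np.searchsorted(edges, c, side="right") - 1  # segment containing c
        idx = np.clip(idx, 0, len(edges) - 1)
        # integral from c to end: full tail from next edge plus partial segment
        next_edge = np.where(idx + 1 < len(edges), edges[np.minimum(idx + 1, len(edges) - 1)], edges[-1])
        partial = np.clip(next_edge - c, 0.0, None) * s[np.minimum(idx, len(s) - 1)]
        integral = np.where(idx + 1 < len(edges), tail[np.minimum(idx + 1, len(tail) - 1)] + partial, 0.0)
        s_c = np.asarray(self.survival_at(c), dtype=float)
        out = np.where(s_c > 0.0, c + integral / np.where(s_c > 0, s_c, 1.0), c)
        return out


def censoring_km(times: np.ndarray, events: np.ndarray) -> KaplanMeier:
    """KM estimate of the censoring distribution G (event/censor roles swapped)."""
    return KaplanMeier.fit(times, 1 - np.asarray(events, dtype=int))
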