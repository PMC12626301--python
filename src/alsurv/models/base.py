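"""Model contract and curve utilities shared by all ISD models."""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from ..config import HORIZON
from ..containers import ISDMatrix, SurvivalDataset, default_time_grid


class SurvivalModel(ABC):
    """A fitted model maps encoded covariates to one survival curve per
    patient (per event for the multi-event model)."""

    model_kind: str = ""
    event_index: int | None = None

    @abstractmethod
    def fit(
        self,
        train: SurvivalDataset,
        validation: SurvivalDataset | None = None,
    ) -> "SurvivalModel":
        ...

    @abstractmethod
    def predict_survival(self, X: np.ndarray, time_grid: np.ndarray | None = None) -> np.ndarray:
        """(n, len(grid)) survival probabilities for this model's event."""
        ...

    def predict_isd(self, X: np.ndarray, time_grid: np.ndarray | None = None) -> ISDMatrix:
        grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
        return ISDMatrix(time_grid=grid, curves=self.predict_survival(X, grid))


def median_survival_time(
    curves: np.ndarray, time_grid: np.ndarray, horizon: int = HORIZON
) -> np.ndarray:
    """Median survival time of each curve: the first grid time where S
    drops to 0.5, linearly interpolated between bracketing grid points.

    Curves still above 0.5 at the end of the grid are linearly
    extrapolated through their last two distinct points, capped at
    ``2 * horizon``; a perfectly flat curve gets the cap itself. The cap
    keeps risk scores finite while preserving their ordering.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    grid = np.asarray(time_grid, dtype=float)
    if curves.shape[-1] != grid.shape[0] or grid.shape[0] < 2:
        raise ValueError("curve/grid length mismatch or grid too short")
    cap = 2.0 * horizon
    n = curves.shape[0]
    out = np.full(n, cap)
    below = curves <= 0.5
    has = below.any(axis=1)
    if has.any():
        rows = np.flatnonzero(has)
        j = np.argmax(below[rows], axis=1)
        nz = j > 0  # S(0)=1 > 0.5, so j=0 only for degenerate curves
        r, jj = rows[nz], j[nz]
        s0 = curves[r, jj - 1]
        s1 = curves[r, jj]
        denom = np.where(s0 == s1, 1.0, s0 - s1)
        out[r] = np.where(
            s0 == s1, grid[jj], grid[jj - 1] + (s0 - 0.5) * (grid[jj] - grid[jj - 1]) / denom
        )
        out[rows[~nz]] = grid[0]
    for i in np.flatnonzero(~has):
        # extrapolate through the last two distinct values
        s = curves[i]
        distinct = np.nonzero(s[:-1] > s[-1])[0]
        if distinct.size == 0:  # flat curve
            out[i] = cap
            continue
        j0 = int(distinct[-1])
        slope = (s[-1] - s[j0]) / (grid[-1] - grid[j0])
        out[i] = min(grid[-1] + (0.5 - s[-1]) / slope, cap)
    return out


def risk_scores(curves: np.ndarray, time_grid: np.ndarray, horizon: int = HORIZON) -> np.ndarray:
    """Negative median survival time: higher risk = earlier predicted event."""
    return -median_survival_time(curves, time_grid, horizon)
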