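"""Random survival forest behind the common model contract.

The ensemble itself (log-rank splitting, leaf-level Nelson-Aalen /
Kaplan-Meier aggregation) is delegated to scikit-survival; this wrapper
only adapts the multi-event dataset and the curve grid.
"""

from __future__ import annotations

import numpy as np
from sksurv.ensemble import RandomSurvivalForest

from ..config import DEFAULTS
from ..containers import SurvivalDataset, default_time_grid
from .base import SurvivalModel


def _sksurv_y(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    return np.array(
        list(zip(events.astype(bool), times.astype(float))),
        dtype=[("event", "?"), ("time", "<f8")],
    )


class SurvivalForestModel(SurvivalModel):
    model_kind = "forest"

    def __init__(self, event_index: int = 0, n_trees: int = DEFAULTS.forest_trees,
                 seed: int = 0, min_samples_leaf: int = 15):
        self.event_index = event_index
        self.n_trees = n_trees
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.forest_: RandomSurvivalForest | None = None

    def fit(self, train: SurvivalDataset, validation=None) -> "SurvivalForestModel":
        X = np.asarray(train.X, dtype=float)
        y = _sksurv_y(train.times[:, self.event_index], train.events[:, self.event_index])
        self.forest_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
            n_jobs=1,
        ).fit(X, y)
        return self

    def predict_survival(self, X: np.ndarray, time_grid=None) -> np.ndarray:
        if self.forest_ is None:
            raise RuntimeError("model not fitted")
        grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
        fns = self.forest_.predict_survival_function(np.asarray(X, float))
        out = np.ones((len(fns), len(grid)))
        for i, fn in enumerate(fns):
            inside = (grid >= fn.domain[0]) & (grid <= fn.domain[1])
            vals = fn(grid[inside])
            out[i, inside] = vals
            # beyond the last training time the curve is carried flat
            beyond = grid > fn.domain[1]
            if beyond.any():
                out[i, beyond] = vals[-1] if vals.size else 1.0
        return np.clip(out, 0.0, 1.0)
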