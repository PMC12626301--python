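"""Covariate-free Kaplan-Meier baseline model."""

from __future__ import annotations

import numpy as np

from ..containers import SurvivalDataset, default_time_grid
from ..nonparametric import KaplanMeier
from .base import SurvivalModel


class KaplanMeierModel(SurvivalModel):
    """Predicts the population product-limit curve for every patient."""

    model_kind = "km"

    def __init__(self, event_index: int = 0):
        self.event_index = event_index
        self.km_: KaplanMeier | None = None

    def fit(self, train: SurvivalDataset, validation=None) -> "KaplanMeierModel":
        times = train.times[:, self.event_index]
        events = train.events[:, self.event_index]
        if times.size == 0:
            raise ValueError("cannot fit on an empty dataset")
        self.km_ = KaplanMeier.fit(times, events)
        return self

    def predict_survival(self, X: np.ndarray, time_grid=None) -> np.ndarray:
        if self.km_ is None:
            raise RuntimeError("model not fitted")
        grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
        curve = self.km_.curve_on_grid(grid)
        n = np.asarray(X).shape[0]
        return np.tile(curve, (n, 1))
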