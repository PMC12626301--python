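"""In-memory containers shared across the pipeline.

The cohort-level multi-event outcome representation is a pair of (N, K)
arrays — observed times ``t`` (integer days in {1..Tmax}) and indicators
``delta`` in {0, 1} — kept alongside the encoded covariate matrix in a
:class:`SurvivalDataset`. Per-patient views exist only at the annotation
boundary (:mod:`alsurv.annotation`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import EVENT_NAMES, HORIZON, N_EVENTS


@dataclass
class SurvivalDataset:
    """Encoded covariates plus multi-event right-censored outcomes.

    Attributes
    ----------
    X:
        (N, d) float covariate matrix. May contain NaN before preprocessing;
        never after :func:`alsurv.preprocessing.transform`.
    times:
        (N, K) integer days, each in {1..Tmax}.
    events:
        (N, K) indicators; 1 = event observed, 0 = right-censored.
    patient_ids:
        Length-N identifier array (kept through splits for traceability).
    feature_names:
        Column names of ``X``.
    event_names:
        Names of the K events, fixed order.
    horizon:
        Tmax in days.
    split_label:
        One of {"train", "validation", "test", "all"}.
    transformed:
        Guard flag set by ``transform``; prevents double application.
    """

    X: np.ndarray
    times: np.ndarray
    events: np.ndarray
    patient_ids: np.ndarray
    feature_names: list[str]
    event_names: tuple[str, ...] = EVENT_NAMES
    horizon: int = HORIZON
    split_label: str = "all"
    transformed: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.X, pd.DataFrame):
            self.X = np.asarray(self.X, dtype=float)
        self.times = np.asarray(self.times)
        self.events = np.asarray(self.events)
        n = self.X.shape[0]
        if not (self.times.shape[0] == self.events.shape[0] == n):
            raise ValueError("X, times and events must have equal row counts")
        if self.times.shape[1] != len(self.event_names):
            raise ValueError(
                f"expected {len(self.event_names)} event columns, "
                f"got {self.times.shape[1]}"
            )
        if np.any(self.times < 1) or np.any(self.times > self.horizon):
            raise ValueError(f"times must lie in [1, {self.horizon}]")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_events(self) -> int:
        return len(self.event_names)

    def subset(self, idx: np.ndarray, split_label: str | None = None) -> "SurvivalDataset":
        """Row subset, preserving metadata."""
        X = self.X.iloc[idx].reset_index(drop=True) if isinstance(self.X, pd.DataFrame) else self.X[idx]
        return replace(
            self,
            X=X,
            times=self.times[idx],
            events=self.events[idx],
            patient_ids=self.patient_ids[idx],
            split_label=split_label or self.split_label,
        )

    @classmethod
    def from_frames(
        cls,
        covariates: pd.DataFrame,
        outcomes: pd.DataFrame,
        feature_columns: list[str] | None = None,
        horizon: int = HORIZON,
    ) -> "SurvivalDataset":
        """Join a covariate table with an annotated outcome table on patient_id.

        ``outcomes`` uses the column layout written by
        :func:`alsurv.annotation.annotate_cohort`: ``patient_id`` then
        ``time_<event>`` / ``event_<event>`` per event.
        """
        merged = covariates.merge(outcomes, on="patient_id", how="inner")
        if feature_columns is None:
            reserved = {"patient_id"} | {
                f"{p}_{e.lower()}" for e in EVENT_NAMES for p in ("time", "event")
            }
            feature_columns = [c for c in covariates.columns if c not in reserved and c != "patient_id"]
        times = merged[[f"time_{e.lower()}" for e in EVENT_NAMES]].to_numpy(dtype=int)
        events = merged[[f"event_{e.lower()}" for e in EVENT_NAMES]].to_numpy(dtype=int)
        # categorical columns stay as object dtype until one-hot encoding,
        # so X is carried as a DataFrame until transform() produces a matrix
        ds = cls.__new__(cls)
        ds.X = merged[feature_columns]  # type: ignore[assignment]
        ds.times = times
        ds.events = events
        ds.patient_ids = merged["patient_id"].to_numpy()
        ds.feature_names = list(feature_columns)
        ds.event_names = EVENT_NAMES
        ds.horizon = horizon
        ds.split_label = "all"
        ds.transformed = False
        return ds


@dataclass
class ISDMatrix:
    """Per-patient, per-event individual survival distributions on a time grid.

    ``curves`` has shape (n_patients, n_events, len(time_grid)); every curve
    starts at 1 at t=0, lies in [0, 1], and is nonincreasing along the grid.
    """

    time_grid: np.ndarray
    curves: np.ndarray
    event_names: tuple[str, ...] = EVENT_NAMES

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim == 2:  # single event convenience
            self.curves = self.curves[:, None, :]
        if self.curves.shape[-1] != self.time_grid.shape[0]:
            raise ValueError("curves last axis must match time_grid length")

    def validate(self, atol: float = 1e-8) -> None:
        """Raise if any curve violates the survival-curve invariants."""
        if self.time_grid[0] != 0:
            raise ValueError("time grid must start at 0")
        if np.any(self.curves < -atol) or np.any(self.curves > 1 + atol):
            raise ValueError("survival probabilities outside [0, 1]")
        if np.any(np.abs(self.curves[..., 0] - 1.0) > atol):
            raise ValueError("S(0) must equal 1")
        if np.any(np.diff(self.curves, axis=-1) > atol):
            raise ValueError("survival curves must be nonincreasing")

    def event_curves(self, event_index: int) -> np.ndarray:
        """(n_patients, n_times) slice for one event."""
        return self.curves[:, event_index, :]


def default_time_grid(horizon: int = HORIZON) -> np.ndarray:
    """Integer-day grid 0..horizon used for all exported ISDs."""
    return np.arange(0, horizon + 1, dtype=float)


@dataclass
class MultiEventOutcome:
    """One patient's K right-censored outcomes (annotation-boundary view)."""

    patient_id: object
    times: np.ndarray
    events: np.ndarray
    event_names: tuple[str, ...] = EVENT_NAMES

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != (N_EVENTS,) or self.events.shape != (N_EVENTS,):
            raise ValueError(f"expected {N_EVENTS} times and indicators")
        if np.any(self.times < 1):
            raise ValueError("times must be >= 1 day")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("indicators must be 0 or 1")
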