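"""Event annotation: longitudinal ALSFRS-R visits -> right-censored outcomes.

An event for a tracked function occurs at the first follow-up visit
(day > 0) where the item score is 2 or fewer; the baseline visit never
triggers an event. Patients already at <= 2 on any tracked item at
baseline are excluded (function lost before study entry), as are patients
with no recorded visit history. A patient with no qualifying follow-up
visit is censored at their last recorded visit day. Finally an
administrative horizon (default 500 days) turns later events into
censoring at the horizon.

The first-crossing rule is strict: a score that dips to 2 and later
recovers still marks the event at the dip. Events are annotated
independently per item; they can occur in any order and are not mutually
exclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EVENT_NAMES, EVENT_SCORE_THRESHOLD, HORIZON
from .containers import MultiEventOutcome

_ITEM_COLS = [e.lower() for e in EVENT_NAMES]


class AnnotationError(ValueError):
    """Raised when a visit history cannot be annotated."""


def annotate_patient(visits: pd.DataFrame, horizon: int = HORIZON) -> MultiEventOutcome:
    """Annotate one patient's sorted visit history into K outcomes.

    Parameters
    ----------
    visits:
        Rows for a single patient with columns ``day`` and the five item
        columns; must include a baseline (day 0) visit.
    horizon:
        Administrative cap in days.
    """
    if len(visits) == 0:
        raise AnnotationError("empty visit history")
    visits = visits.sort_values("day")
    days = visits["day"].to_numpy()
    if days[0] != 0:
        raise AnnotationError("no baseline (day 0) visit")
    scores = visits[_ITEM_COLS].to_numpy()
    if np.any(scores < 0) or np.any(scores > 4):
        raise AnnotationError("item score outside 0-4")
    last_day = max(int(days[-1]), 1)  # censoring times live in {1..Tmax}
    followup = days > 0
    times = np.empty(len(EVENT_NAMES), dtype=int)
    events = np.empty(len(EVENT_NAMES), dtype=int)
    for k in range(len(EVENT_NAMES)):
        crossed = followup & (scores[:, k] <= EVENT_SCORE_THRESHOLD)
        if crossed.any():
            times[k] = int(days[np.argmax(crossed)])
            events[k] = 1
        else:
            times[k] = last_day
            events[k] = 0
    outcome = MultiEventOutcome(
        patient_id=visits["patient_id"].iloc[0] if "patient_id" in visits else None,
        times=times,
        events=events,
    )
    return apply_horizon(outcome, horizon)


def apply_horizon(outcome: MultiEventOutcome, horizon: int = HORIZON) -> MultiEventOutcome:
    """Cap outcomes at the administrative horizon (inclusive boundary).

    A time strictly beyond the horizon becomes censoring at the horizon;
    an event exactly at the horizon still counts as observed.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    times = outcome.times.copy()
    events = outcome.events.copy()
    over = times > horizon
    times[over] = horizon
    events[over] = 0
    return MultiEventOutcome(outcome.patient_id, times, events, outcome.event_names)


def filter_cohort(
    visits: pd.DataFrame, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion rules; returns (eligible covariates, exclusion log).

    Excluded are patients whose baseline visit scores <= 2 on any tracked
    item (function lost before entry) and patients present in the
    covariate table but with no visit rows at all.
    """
    log_rows: list[dict] = []
    with_history = set(visits["patient_id"].unique())
    baseline = visits[visits["day"] == 0].set_index("patient_id")
    eligible_ids = []
    for pid in covariates["patient_id"]:
        if pid not in with_history:
            log_rows.append({"patient_id": pid, "reason": "no ALSFRS-R history"})
            continue
        if pid in baseline.index:
            row = baseline.loc[pid]
            impaired = [
                name
                for name, col in zip(EVENT_NAMES, _ITEM_COLS)
                if row[col] <= EVENT_SCORE_THRESHOLD
            ]
            if impaired:
                log_rows.append(
                    {
                        "patient_id": pid,
                        "reason": f"baseline impairment: {', '.join(impaired)}",
                    }
                )
                continue
        eligible_ids.append(pid)
    eligible = covariates[covariates["patient_id"].isin(eligible_ids)].reset_index(drop=True)
    exclusions = pd.DataFrame(log_rows, columns=["patient_id", "reason"])
    return eligible, exclusions


def annotate_cohort(
    visits: pd.DataFrame,
    covariates: pd.DataFrame,
    horizon: int = HORIZON,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter and annotate a whole cohort.

    Returns ``(outcomes, exclusions)`` where outcomes has columns
    ``patient_id`` then ``time_<event>``/``event_<event>`` per event in
    fixed order.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    eligible, exclusions = filter_cohort(visits, covariates)
    keep = eligible["patient_id"]
    v = visits[visits["patient_id"].isin(set(keep))]
    if np.any(v[_ITEM_COLS].to_numpy() < 0) or np.any(v[_ITEM_COLS].to_numpy() > 4):
        raise AnnotationError("item score outside 0-4")
    grouped = v.groupby("patient_id")
    if (grouped["day"].min() != 0).any():
        raise AnnotationError("a retained patient lacks a baseline (day 0) visit")
    last_day = grouped["day"].max().clip(lower=1)
    outcomes = pd.DataFrame({"patient_id": last_day.index})
    followup = v[v["day"] > 0]
    for name, col in zip(EVENT_NAMES, _ITEM_COLS):
        crossed = followup[followup[col] <= EVENT_SCORE_THRESHOLD]
        first = crossed.groupby("patient_id")["day"].min().reindex(last_day.index)
        t = first.fillna(last_day).astype(int)
        d = first.notna().astype(int)
        over = t > horizon
        t[over] = horizon
        d[over] = 0
        outcomes[f"time_{name.lower()}"] = t.to_numpy()
        outcomes[f"event_{name.lower()}"] = d.to_numpy()
    return outcomes.reset_index(drop=True), exclusions


def compute_progression_rate(total_score: float, days_since_diagnosis: float) -> float:
    """Disease progression rate in ALSFRS-R points per month:
    (48 - total) / (days since diagnosis / 30)."""
    if days_since_diagnosis <= 0:
        raise ValueError("days_since_diagnosis must be positive")
    if not 0 <= total_score <= 48:
        raise ValueError("total score must lie in [0, 48]")
    return (48.0 - total_score) / (days_since_diagnosis / 30.0)
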