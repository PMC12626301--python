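"""Experiment orchestration: seeded benchmark loop, counterfactual
predictions, and group-level log-rank comparisons.

The benchmark repeats the full split -> preprocess -> fit -> evaluate
pipeline over a set of stratification seeds (0-9 by default) and
aggregates metrics as mean +/- SD, with D-calibration reported as a pass
count across seeds. Counterfactual predictions flip one covariate of one
patient while holding all others fixed; they are associational model
predictions, labelled "predicted" throughout, not causal estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test

from .config import EVENT_NAMES, HORIZON
from .containers import SurvivalDataset, ISDMatrix, default_time_grid
from .metrics import evaluate_single_event
from .models import MULTI_EVENT_MODELS, SINGLE_EVENT_MODELS, MensaModel, median_survival_time
from .preprocessing import PreprocessorState, preprocess_splits, stratified_split, transform_frame

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# multiple-comparison configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonConfig:
    """Family-wise error control for the five per-event comparisons."""

    alpha: float = 0.05
    n_comparisons: int = 5

    @property
    def alpha_adjusted(self) -> float:
        """Bonferroni-adjusted per-test level: alpha / n_comparisons."""
        return self.alpha / self.n_comparisons


# ---------------------------------------------------------------------------
# counterfactual predictions
# ---------------------------------------------------------------------------

@dataclass
class CounterfactualQuery:
    """One patient, one covariate, a list of alternative values."""

    patient: pd.Series
    covariate: str
    alternatives: list

    def __post_init__(self) -> None:
        if self.covariate not in self.patient.index:
            raise ValueError(f"unknown covariate {self.covariate!r}")


def predict_counterfactual(
    model,
    preprocessor: PreprocessorState,
    query: CounterfactualQuery,
    time_grid: np.ndarray | None = None,
) -> tuple[list[ISDMatrix], pd.DataFrame]:
    """Predicted ISDs under each alternative value of one covariate.

    Returns one K-event ISD per alternative (single-event models produce a
    one-event ISD) and a table of predicted median survival times per
    event and alternative. The factual patient record is never mutated.
    """
    grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
    isds: list[ISDMatrix] = []
    rows = []
    for value in query.alternatives:
        patient = query.patient.copy()
        if query.covariate in preprocessor.categorical_columns:
            if value not in preprocessor.vocabularies[query.covariate]:
                raise ValueError(
                    f"cannot encode unseen category {value!r} for {query.covariate!r}"
                )
        patient[query.covariate] = value
        X = transform_frame(preprocessor, patient.to_frame().T)
        if isinstance(model, MensaModel):
            curves = model.predict_survival_all(X, grid)  # (1, K, T)
            names = EVENT_NAMES
        else:
            curves = model.predict_survival(X, grid)[:, None, :]
            names = (EVENT_NAMES[model.event_index],)
        isds.append(ISDMatrix(time_grid=grid, curves=curves, event_names=names))
        for k, name in enumerate(names):
            med = median_survival_time(curves[:, k, :], grid)[0]
            rows.append({"alternative": value, "event": name, "predicted_median_days": med})
    medians = pd.DataFrame(rows)
    return isds, medians


def group_logrank(
    times: np.ndarray,
    indicators: np.ndarray,
    groups: np.ndarray,
    config: ComparisonConfig = ComparisonConfig(),
) -> tuple[float, float, bool]:
    """Two-group log-rank test on one event's observed (t, delta).

    ``groups`` must contain exactly two distinct values; numeric
    covariates should be split at the median upstream. Significance is
    declared at the Bonferroni-adjusted level.
    """
    groups = np.asarray(groups)
    values = pd.unique(groups)
    if len(values) != 2:
        raise ValueError(f"need exactly two groups, got {len(values)}")
    a = groups == values[0]
    b = groups == values[1]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("a group has zero members")
    res = logrank_test(
        np.asarray(times)[a], np.asarray(times)[b],
        event_observed_A=np.asarray(indicators)[a],
        event_observed_B=np.asarray(indicators)[b],
    )
    return float(res.test_statistic), float(res.p_value), bool(res.p_value < config.alpha_adjusted)


# ---------------------------------------------------------------------------
# benchmark loop
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    models: list = field(default_factory=lambda: ["km", "coxph", "mtlr", "deepcox", "forest", "mensa"])
    seeds: list = field(default_factory=lambda: list(range(10)))
    model_options: dict = field(default_factory=dict)  # name -> constructor kwargs
    horizon: int = HORIZON


def _make_model(name: str, event_index: int, seed: int, options: dict):
    kwargs = dict(options.get(name, {}))
    if name in SINGLE_EVENT_MODELS:
        cls = SINGLE_EVENT_MODELS[name]
        if name in ("deepcox", "forest"):
            kwargs.setdefault("seed", seed)
        return cls(event_index=event_index, **kwargs)
    cls = MULTI_EVENT_MODELS[name]
    kwargs.setdefault("seed", seed)
    return cls(**kwargs)


def run_benchmark(
    dataset: SurvivalDataset, config: BenchmarkConfig = BenchmarkConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-seed train/evaluate loop over all requested models and events.

    Returns ``(per_seed, aggregate)``: one row per model x event x seed,
    and the mean +/- SD aggregation with D-calibration pass counts.
    Failures in a single seed are logged and skipped; the loop continues.
    """
    if not config.models or not config.seeds:
        raise ValueError("need at least one model and one seed")
    grid = default_time_grid(config.horizon)
    rows = []
    for seed in config.seeds:
        train_raw, val_raw, test_raw = stratified_split(dataset, seed=seed)
        train, val, test, _state = preprocess_splits(train_raw, val_raw, test_raw)
        for name in config.models:
            try:
                if name in MULTI_EVENT_MODELS:
                    model = _make_model(name, 0, seed, config.model_options)
                    model.fit(train, val)
                    curves_all = model.predict_survival_all(test.X, grid)
                    per_event_curves = [curves_all[:, k, :] for k in range(len(EVENT_NAMES))]
                else:
                    per_event_curves = []
                    for k in range(len(EVENT_NAMES)):
                        model = _make_model(name, k, seed, config.model_options)
                        model.fit(train, val)
                        per_event_curves.append(model.predict_survival(test.X, grid))
                for k, event in enumerate(EVENT_NAMES):
                    res = evaluate_single_event(
                        per_event_curves[k], grid,
                        test.times[:, k], test.events[:, k],
                        train.times[:, k], train.events[:, k],
                        horizon=config.horizon,
                    )
                    rows.append({"model": name, "event": event, "seed": seed, **res})
            except Exception:  # noqa: BLE001 - per-seed failures do not abort the run
                log.exception("model %s failed on seed %d", name, seed)
    per_seed = pd.DataFrame(rows)
    if per_seed.empty:
        raise RuntimeError("every model/seed combination failed")
    metrics = ["harrell_ci", "uno_ci", "ibs", "mmae"]
    agg = per_seed.groupby(["model", "event"], sort=False).agg(
        **{f"{m}_mean": (m, "mean") for m in metrics},
        **{f"{m}_sd": (m, lambda s: s.std(ddof=1) if len(s) > 1 else 0.0) for m in metrics},
        dcal_passes=("dcal_pass", "sum"),
        n_seeds=("seed", "count"),
    ).reset_index()
    return per_seed, agg


def benchmark_report(agg: pd.DataFrame) -> pd.DataFrame:
    """Presentation layer: concordance and IBS scaled x100, mMAE in days."""
    out = agg.copy()
    for m in ("harrell_ci", "uno_ci", "ibs"):
        out[f"{m}_mean"] = out[f"{m}_mean"] * 100
        out[f"{m}_sd"] = out[f"{m}_sd"] * 100
    return out
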