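"""Splitting and covariate preprocessing.

The 70/10/20 split uses iterative multi-label stratification so that, for
every one of the K events, both the censoring rate and the distribution of
observed times stay consistent across train/validation/test. Each patient
carries one label per event: the event indicator crossed with the tercile
of the observed time, giving up to 6 label values per event.

Imputation (training mean for numeric, training mode for categorical),
one-hot encoding with a full indicator block, and z-score normalization
are all fitted on the training split only and applied as a pure function
of that fitted state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import SurvivalDataset


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

def _largest_remainder_sizes(n: int, fractions: tuple[float, ...]) -> list[int]:
    raw = [n * f for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - r for s, r in zip(sizes, raw)])  # most-negative first
    for i in range(rem):
        sizes[order[i]] += 1
    return sizes


def _event_time_labels(ds: SurvivalDataset) -> np.ndarray:
    """(N, K) integer labels: indicator crossed with observed-time tercile."""
    n, k = ds.times.shape
    labels = np.empty((n, k), dtype=int)
    for j in range(k):
        t = ds.times[:, j]
        edges = np.quantile(t, [1 / 3, 2 / 3])
        terc = np.searchsorted(edges, t, side="right")
        labels[:, j] = j * 6 + ds.events[:, j] * 3 + terc
    return labels


def stratified_split(
    ds: SurvivalDataset,
    fractions: tuple[float, float, float] = (0.70, 0.10, 0.20),
    seed: int = 0,
) -> tuple[SurvivalDataset, SurvivalDataset, SurvivalDataset]:
    """Iterative multi-label stratified partition into train/validation/test.

    Greedy Sechidis-style assignment: repeatedly take the label with the
    fewest unassigned patients, and place each of its patients into the
    subset with the greatest remaining demand for that label (ties broken
    by overall remaining capacity, then at random under ``seed``).
    """
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = ds.n
    if n < 10:
        raise ValueError("need at least 10 patients to split")
    rng = np.random.default_rng(seed)
    sizes = _largest_remainder_sizes(n, fractions)
    labels = _event_time_labels(ds)
    n_subsets = len(fractions)
    label_values = np.unique(labels)
    # desired per-subset counts for every label, largest-remainder rounded
    desired = {}
    for lv in label_values:
        count = int((labels == lv).any(axis=1).sum())
        desired[lv] = np.array(_largest_remainder_sizes(count, fractions), dtype=float)
    capacity = np.array(sizes, dtype=float)
    assignment = np.full(n, -1, dtype=int)
    unassigned = set(range(n))
    label_members: dict[int, set[int]] = {
        int(lv): set(np.nonzero((labels == lv).any(axis=1))[0]) for lv in label_values
    }
    while unassigned:
        # label with fewest remaining unassigned members (non-empty)
        remaining = {
            lv: members & unassigned for lv, members in label_members.items()
        }
        remaining = {lv: m for lv, m in remaining.items() if m}
        if remaining:
            lv = min(remaining, key=lambda v: (len(remaining[v]), v))
            members = sorted(remaining[lv])
        else:  # no labels left (cannot happen: every patient has K labels)
            members = sorted(unassigned)
            lv = None
        for i in members:
            if lv is not None:
                demand = desired[lv].copy()
            else:
                demand = capacity.copy()
            best = np.flatnonzero(demand == demand.max())
            if len(best) > 1:
                caps = capacity[best]
                best = best[np.flatnonzero(caps == caps.max())]
            choice = int(best[0]) if len(best) == 1 else int(rng.choice(best))
            if capacity[choice] <= 0:  # subset full; fall back to open capacity
                choice = int(np.argmax(capacity))
            assignment[i] = choice
            capacity[choice] -= 1
            unassigned.discard(i)
            for row_lv in labels[i]:
                desired[int(row_lv)][choice] -= 1
    idx = [np.flatnonzero(assignment == s) for s in range(n_subsets)]
    names = ("train", "validation", "test")
    return tuple(ds.subset(ix, split_label=nm) for ix, nm in zip(idx, names))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# preprocessing state
# ---------------------------------------------------------------------------

@dataclass
class PreprocessorState:
    """Training-split statistics; transformation is a pure function of this."""

    numeric_columns: list[str] = field(default_factory=list)
    categorical_columns: list[str] = field(default_factory=list)
    impute_values: dict = field(default_factory=dict)      # column -> mean or mode
    vocabularies: dict = field(default_factory=dict)       # column -> sorted categories
    means: dict = field(default_factory=dict)              # numeric column -> train mean
    scales: dict = field(default_factory=dict)             # numeric column -> train sd (>=: 1 if 0)
    fitted_on: str = ""

    @property
    def feature_names(self) -> list[str]:
        names = list(self.numeric_columns)
        for c in self.categorical_columns:
            names += [f"{c}={v}" for v in self.vocabularies[c]]
        return names


def fit_preprocessor(train: SurvivalDataset) -> PreprocessorState:
    """Learn imputation, vocabulary and scaling constants from training data."""
    X = train.X
    if not isinstance(X, pd.DataFrame):
        raise TypeError("fit_preprocessor expects raw (DataFrame) covariates")
    if len(X) == 0:
        raise ValueError("empty training split")
    state = PreprocessorState(fitted_on=train.split_label)
    for col in X.columns:
        series = X[col]
        if pd.api.types.is_numeric_dtype(series):
            observed = series.dropna()
            if observed.empty:
                raise ValueError(f"column {col!r} is entirely missing")
            state.numeric_columns.append(col)
            state.impute_values[col] = float(observed.mean())
            filled = series.fillna(state.impute_values[col])
            state.means[col] = float(filled.mean())
            sd = float(filled.std(ddof=0))
            state.scales[col] = sd if sd > 0 else 1.0  # constant column -> zeros
        else:
            observed = series.dropna()
            if observed.empty:
                raise ValueError(f"column {col!r} is entirely missing")
            state.categorical_columns.append(col)
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            state.impute_values[col] = sorted(top)[0]  # lexicographic tie-break
            state.vocabularies[col] = sorted(observed.unique())
    return state


def transform(state: PreprocessorState, data: SurvivalDataset) -> SurvivalDataset:
    """Impute, one-hot encode and z-score ``data`` using training statistics.

    Unseen categories map to an all-zero indicator block. Guarded against
    double application via the dataset's ``transformed`` flag.
    """
    if data.transformed:
        raise ValueError("dataset is already transformed")
    X = data.X
    if not isinstance(X, pd.DataFrame):
        raise TypeError("transform expects raw (DataFrame) covariates")
    mat = transform_frame(state, X)
    out = replace(
        data,
        X=mat,
        feature_names=state.feature_names,
        transformed=True,
    )
    return out


def transform_frame(state: PreprocessorState, X: pd.DataFrame) -> np.ndarray:
    """Encode a raw covariate frame into the fitted numeric design matrix."""
    blocks = []
    for col in state.numeric_columns:
        # single-row frames (counterfactual queries) arrive as object dtype
        v = pd.to_numeric(X[col], errors="coerce").fillna(state.impute_values[col]).to_numpy(dtype=float)
        blocks.append((v - state.means[col]) / state.scales[col])
    for col in state.categorical_columns:
        v = X[col].fillna(state.impute_values[col])
        vocab = state.vocabularies[col]
        onehot = np.zeros((len(X), len(vocab)))
        for j, cat in enumerate(vocab):
            onehot[:, j] = (v == cat).to_numpy(dtype=float)
        blocks.append(onehot)  # unseen categories leave an all-zero block
    return np.column_stack([b if b.ndim == 2 else b[:, None] for b in blocks])


def preprocess_splits(
    train: SurvivalDataset,
    validation: SurvivalDataset,
    test: SurvivalDataset,
) -> tuple[SurvivalDataset, SurvivalDataset, SurvivalDataset, PreprocessorState]:
    """Fit on train, transform all three splits."""
    state = fit_preprocessor(train)
    return (
        transform(state, train),
        transform(state, validation),
        transform(state, test),
        state,
    )
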