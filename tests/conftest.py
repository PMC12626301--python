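import numpy as np
import pytest

import alsurv
from alsurv.cohort import CohortConfig
from alsurv.containers import SurvivalDataset
from alsurv.preprocessing import preprocess_splits, stratified_split


@pytest.fixture(scope="session")
def default_cohort_dataset() -> SurvivalDataset:
    """A 2000-patient default synthetic cohort, annotated and model-ready."""
    return alsurv.build_dataset(CohortConfig(n_patients=2000, seed=0))


@pytest.fixture(scope="session")
def encoded_splits(default_cohort_dataset):
    """Stratified 70/10/20 splits of the default cohort, fully encoded."""
    tr, va, te = stratified_split(default_cohort_dataset, seed=0)
    return preprocess_splits(tr, va, te)


def single_event_dataset(times, events, X=None) -> SurvivalDataset:
    """Wrap a single-event sample as a K=1 SurvivalDataset (test helper)."""
    times = np.asarray(times)
    events = np.asarray(events)
    n = len(times)
    if X is None:
        X = np.zeros((n, 1))
    return SurvivalDataset(
        X=np.asarray(X, float),
        times=times[:, None],
        events=events[:, None],
        patient_ids=np.arange(n),
        feature_names=[f"x{i}" for i in range(np.asarray(X).shape[1])],
        event_names=("Speech",),
        horizon=max(500, int(times.max())),
        transformed=True,
    )
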