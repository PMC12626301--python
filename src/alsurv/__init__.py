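"""Multi-event survival analysis of functional decline in ALS.

Annotates five ALSFRS-R-derived events (Speech, Swallowing, Handwriting,
Walking, Dyspnea) from longitudinal visit records, fits individual-
survival-distribution models — including a jointly trained multi-event
mixture-of-Weibull network — and evaluates them with censoring-aware
discrimination, error and calibration metrics. A synthetic cohort
generator with a known Weibull accelerated-failure-time ground truth
stands in for access-restricted clinical-trial data.
"""

from . import annotation, cohort, config, containers, metrics, models, preprocessing
from .annotation import annotate_cohort, annotate_patient, compute_progression_rate, filter_cohort
from .cohort import CohortConfig, generate_cohort
from .containers import ISDMatrix, MultiEventOutcome, SurvivalDataset, default_time_grid
from .experiment import (
    BenchmarkConfig,
    ComparisonConfig,
    CounterfactualQuery,
    group_logrank,
    predict_counterfactual,
    run_benchmark,
)
from .models import median_survival_time, risk_scores
from .preprocessing import fit_preprocessor, preprocess_splits, stratified_split, transform

__version__ = "0.1.0"


def build_dataset(cohort_config: CohortConfig) -> SurvivalDataset:
    """Generate a synthetic cohort and annotate it into a model-ready dataset."""
    visits, covariates, _truth = generate_cohort(cohort_config)
    outcomes, _exclusions = annotate_cohort(visits, covariates, horizon=cohort_config.admin_horizon)
    eligible = covariates[covariates["patient_id"].isin(outcomes["patient_id"])]
    return SurvivalDataset.from_frames(eligible, outcomes, horizon=cohort_config.admin_horizon)
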