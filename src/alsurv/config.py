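"""Global constants and default hyperparameters.

All model defaults live here so a benchmark run is fully described by one
:class:`ModelDefaults` instance; none of the models perform hyperparameter
search.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The five ALSFRS-R functions tracked as events, in fixed order.
EVENT_NAMES: tuple[str, ...] = (
    "Speech",
    "Swallowing",
    "Handwriting",
    "Walking",
    "Dyspnea",
)

#: Number of events K.
N_EVENTS: int = len(EVENT_NAMES)

#: Administrative follow-up horizon in days (Tmax).
HORIZON: int = 500

#: ALSFRS-R item score below or at which the function is considered lost.
EVENT_SCORE_THRESHOLD: int = 2


@dataclass(frozen=True)
class ModelDefaults:
    """Default hyperparameters shared by the benchmark.

    Attributes
    ----------
    hidden:
        Width of the single hidden layer used by the neural models.
    patience:
        Early-stopping patience in epochs (validation loss).
    max_epochs:
        Upper bound on training epochs for the gradient-trained models.
    batch_size:
        Minibatch size for gradient training.
    learning_rate:
        Adam step size.
    mtlr_bins:
        Number of discrete time intervals for the multi-task logistic model.
    mtlr_l2:
        L2 penalty strength on the MTLR weight matrix.
    mensa_components:
        Mixture components per event (G) for the Weibull-mixture network.
    forest_trees:
        Number of trees in the random survival forest.
    cox_ridge:
        Ridge jitter added to the partial-likelihood Hessian on
        ill-conditioned designs.
    """

    hidden: int = 32
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    mtlr_bins: int = 20
    mtlr_l2: float = 1.0
    mensa_components: int = 3
    forest_trees: int = 100
    cox_ridge: float = 1e-6


DEFAULTS = ModelDefaults()
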