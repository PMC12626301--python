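"""Annotate the five functional-decline events from the visit histories.

An event occurs at the first follow-up visit with an item score of 2 or
less; patients impaired at baseline or without visit history are
excluded; everything is capped at the 500-day horizon.
"""

import argparse
from pathlib import Path

from alsurv.annotation import annotate_cohort
from alsurv.cohort import read_cohort
from alsurv.config import EVENT_NAMES, HORIZON

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--horizon", type=int, default=HORIZON)
args = parser.parse_args()

visits, covariates = read_cohort(args.cohort)
outcomes, exclusions = annotate_cohort(visits, covariates, horizon=args.horizon)
outcomes.to_csv(args.cohort / "outcomes.csv", index=False)
exclusions.to_csv(args.cohort / "exclusions.csv", index=False)

print(f"annotated {len(outcomes)} patients ({len(exclusions)} excluded)")
print(f"{'event':<14}{'uncensored %':>14}")
for e in EVENT_NAMES:
    frac = outcomes[f"event_{e.lower()}"].mean()
    print(f"{e:<14}{100 * frac:>13.1f}")
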