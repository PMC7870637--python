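"""Calibration of the Alvarado item probabilities in the cohort generator.

The generator draws the eight score items as independent Bernoulli
variables conditional on disease status.  The source cohort reports only
the median total score by group (7 with appendicitis, 4 without), not
item frequencies, so the itemwise probabilities are free parameters.
This script simulates the implied score distribution for the frozen
defaults (and any candidate vector you edit in) and prints the median,
mean, and tail masses, which is how the shipped defaults in
``dialapp.cohort`` were chosen: plausible item frequencies (tenderness
nearly universal in disease, laboratory signs common, every item rarer
without disease) adjusted until the simulated medians are 7 and 4.

Run:  python scripts/calibrate_components.py [--n 200000] [--seed 0]
"""

from __future__ import annotations

import argparse

import numpy as np

from dialapp.alvarado import ITEM_WEIGHTS
from dialapp.cohort import COMPONENT_PROBS_DISEASED, COMPONENT_PROBS_HEALTHY

TARGET_MEDIANS = {"diseased": 7, "healthy": 4}


def summarize(name: str, probs, n: int, rng) -> None:
    weights = np.array(list(ITEM_WEIGHTS.values()))
    draws = rng.random((n, 8)) < np.asarray(probs)
    scores = draws @ weights
    median = float(np.median(scores))
    status = "OK" if median == TARGET_MEDIANS[name] else "OFF TARGET"
    print(
        f"{name:9s} probs={list(probs)}\n"
        f"  median={median:.1f} (target {TARGET_MEDIANS[name]}) [{status}]  "
        f"mean={scores.mean():.2f}  "
        f"P(score<=4)={float((scores <= 4).mean()):.3f}  "
        f"P(5<=score<=8)={float(((scores >= 5) & (scores <= 8)).mean()):.3f}  "
        f"P(score>=9)={float((scores >= 9).mean()):.3f}"
    )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=200_000, help="simulated patients per group")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    summarize("diseased", COMPONENT_PROBS_DISEASED, args.n, rng)
    summarize("healthy", COMPONENT_PROBS_HEALTHY, args.n, rng)


if __name__ == "__main__":
    main()
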