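#!/usr/bin/env python
"""Score the coordination hypotheses against observed dyad durations.

By default the observed durations are the synthetic cohort's segmented
dyadic movements (results/segments.csv); pass a CSV path with columns
(condition, target_index, observed_T) to validate against externally
measured data instead.  Writes results/comparison.json with the median
absolute duration error per hypothesis and stiffness family plus the
qualitative checklist.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from dyadvigor import compare_hypotheses
from dyadvigor.pipeline import load_observed_durations

ROOT = Path(__file__).resolve().parents[1] / "results"


def observed_from_segments() -> pd.DataFrame:
    segs = pd.read_csv(ROOT / "segments.csv")
    dyadic = segs[segs.condition.str.startswith("K")]
    obs = (dyadic.groupby(["condition", "target_index"])["duration"]
           .mean().rename("observed_T").reset_index())
    return obs


def main():
    pred = pd.read_csv(ROOT / "predictions.csv")
    if len(sys.argv) > 1:
        obs = load_observed_durations(sys.argv[1])
        src = sys.argv[1]
    else:
        obs = observed_from_segments()
        src = "synthetic cohort"
    report = compare_hypotheses(pred, obs)
    (ROOT / "comparison.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    print(f"observed durations: {src}")
    piv = report.medians.pivot(index="hypothesis", columns="family",
                               values="median_error_s") * 1000
    print("median |T_pred - T_obs| (ms):")
    print(piv.round(1))
    print("checklist:", report.checklist)


if __name__ == "__main__":
    main()
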