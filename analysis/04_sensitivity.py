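"""Sensitivity analyses on the prediction-outcome pairs.

1. Does race moderate predictive performance?  Mixed model with person
   random intercept; joint F test on prediction x race interactions.
2. Is the prediction slope robust to controlling for the previous-hour
   outcome (i.e., is the model doing more than carrying the last
   observation forward)?

Usage: python analysis/04_sensitivity.py [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

import moodcast as mc
from moodcast.exceptions import MoodcastError
from moodcast.sensitivity import sensitivity_report_lines


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    preds = pd.read_csv(args.out / "predictions.csv", dtype={"person_id": str})
    panel = mc.read_panel(args.out / "panel.csv")
    pairs = mc.pool_imputations(preds)

    moderation = lagged = None
    try:
        moderation = mc.race_moderation_test(pairs, panel.profiles)
    except MoodcastError as exc:
        print(f"race moderation not testable: {exc}")
    try:
        lagged = mc.lagged_outcome_test(pairs)
    except MoodcastError as exc:
        print(f"lagged control not testable: {exc}")

    lines = sensitivity_report_lines(moderation, lagged)
    for line in lines:
        print(line)
    (args.out / "sensitivity.txt").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
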