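"""Out-of-sample agreement: pooled and per-person predicted-vs-observed
correlations, Fisher-z averaged, with forest and trajectory figures.

Usage: python analysis/03_evaluate.py [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

import moodcast as mc
from moodcast.evaluation import plot_forest, plot_trajectories, write_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    preds = pd.read_csv(args.out / "predictions.csv", dtype={"person_id": str})
    pooled_pairs = mc.pool_imputations(preds)
    pooled = mc.pooled_correlation(
        pooled_pairs["y_observed"], pooled_pairs["yhat_idiographic"]
    )
    summary = mc.summarize_idiographic(pooled_pairs)

    write_report(args.out, pooled, summary)
    plot_forest(summary, args.out / "per_person_forest.png")
    plot_trajectories(pooled_pairs, args.out / "trajectories.png")

    print(f"pooled r = {pooled.r:.3f}, 95% CI [{pooled.ci_low:.3f}, {pooled.ci_high:.3f}], "
          f"n = {pooled.n} person-hours")
    print(f"Fisher-z average per-person r = {summary.average_r:.3f}, "
          f"95% CI [{summary.average_ci[0]:.3f}, {summary.average_ci[1]:.3f}]")
    best = max(summary.per_person.items(), key=lambda kv: kv[1].r)
    print(f"strongest per-person correlation: {best[0]} r = {best[1].r:.3f}")
    if summary.excluded:
        print(f"{len(summary.excluded)} persons excluded (undefined/insufficient)")


if __name__ == "__main__":
    main()
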