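#!/usr/bin/env python
"""Stage 5: per-subject fits and group-level summaries of the ratings.

Reads the rating datasets from stage 4, fits each Experiment 1 subject's
rating-versus-stiffness line (slope, R^2, Pearson r), summarizes both
experiments (rating curves, between-condition ANOVA, paired condition
contrasts) and writes results/fits_exp1.csv and results/report.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from stiffsim import fit_all_subjects, summarize

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ratings1 = pd.read_csv(RESULTS / "ratings_exp1.csv")
    ratings2 = pd.read_csv(RESULTS / "ratings_exp2.csv")

    fits1 = fit_all_subjects(ratings1)
    fits1.to_csv(RESULTS / "fits_exp1.csv", index=False)

    report = {
        "experiment_1": summarize(ratings1, fits1),
        "experiment_2": summarize(ratings2),
    }
    (RESULTS / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    print("Experiment 1 per-subject fits:")
    print(fits1.round(4).to_string(index=False))
    print(f"\nmean R^2 = {fits1['r_squared'].mean():.3f}, "
          f"mean slope = {fits1['slope'].mean():.4f} per N*m/rad")
    means = report["experiment_2"]["condition_means"]
    print("\nExperiment 2 mean rating by timing condition:")
    for cond, stats in sorted(means.items(), key=lambda kv: kv[1]["mean"]):
        print(f"  {cond:>9}: {stats['mean']:.3f} +/- {stats['two_se']:.3f} (2 SE)")
    print(f"\nwrote {RESULTS / 'fits_exp1.csv'} and {RESULTS / 'report.json'}")


if __name__ == "__main__":
    main()
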