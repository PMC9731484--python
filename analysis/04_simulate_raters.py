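#!/usr/bin/env python
"""Stage 4: generate synthetic Likert ratings for both experiments.

Reads results/features.csv, builds the blocked randomized trial schedules
(Experiment 1: 10 subjects x 5 blocks x 6 stimuli, timing condition between
subjects; Experiment 2: 10 subjects x 5 blocks x 4 conditions of one path)
and simulates 7-point stiffness ratings with the latent linear rater model.
Experiment 2 raters carry a temporal penalty against the veridically timed
profile. Seeds match the end-to-end pipeline defaults so the staged run and
`run_pipeline` produce identical datasets.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dataclasses import replace

from stiffsim import SubjectModel, build_design, generate_ratings

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    features = pd.read_csv(RESULTS / "features.csv")
    model = SubjectModel()

    design1 = build_design(1, n_subjects=10, rng_seed=SEED)
    ratings1 = generate_ratings(design1, features, model, rng_seed=SEED + 10)
    ratings1.to_csv(RESULTS / "ratings_exp1.csv", index=False)

    design2 = build_design(2, n_subjects=10, rng_seed=SEED + 1)
    model2 = replace(model, temporal_penalty=0.5)
    ratings2 = generate_ratings(design2, features, model2, rng_seed=SEED + 11)
    ratings2.to_csv(RESULTS / "ratings_exp2.csv", index=False)

    for name, ratings in (("exp1", ratings1), ("exp2", ratings2)):
        print(f"{name}: {len(ratings)} trials, "
              f"{ratings['subject_id'].nunique()} subjects, "
              f"mean rating {ratings['rating'].mean():.3f}")
    print(f"wrote rating datasets to {RESULTS}")


if __name__ == "__main__":
    main()
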