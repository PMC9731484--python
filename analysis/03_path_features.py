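#!/usr/bin/env python
"""Stage 3: extract path and temporal features from every stimulus.

Reads the stimuli written by stage 2 and computes, per stimulus, the path
features (centroid, oblongness, enclosed area, mean curvature, joint ranges of
motion) and the temporal features (relative phase, RMS endpoint speed,
acceleration and jerk), writing results/features.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from stiffsim import feature_table, load_trajectory
from stiffsim.timing import Stimulus

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    stimdir = RESULTS / "stimuli"
    manifest = pd.read_csv(stimdir / "manifest.csv")
    stimuli = []
    for row in manifest.itertuples():
        traj, profile = load_trajectory(stimdir / row.file)
        stimuli.append(
            Stimulus(
                traj=traj,
                profile=profile,
                E=float(row.E),
                condition=str(row.condition),
                display_loops=int(row.display_loops),
            )
        )
    features = feature_table(stimuli).drop_duplicates(
        subset=["condition", "E"]
    ).reset_index(drop=True)
    features.to_csv(RESULTS / "features.csv", index=False)
    with pd.option_context("display.width", 160):
        print(features.round(4).to_string(index=False))
    print(f"wrote {len(features)} feature rows to {RESULTS / 'features.csv'}")


if __name__ == "__main__":
    main()
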