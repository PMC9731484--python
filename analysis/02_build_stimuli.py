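#!/usr/bin/env python
"""Stage 2: retime the steady cycles into the four timing conditions.

Reads the steady cycles written by stage 1, builds the Experiment 1 stimulus
set (6 stiffness levels x 4 timing conditions) and the Experiment 2 set (the
E = 30 N*m/rad path under all four conditions), and writes each retimed
stimulus plus a manifest to results/stimuli/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from stiffsim import StimulusSetConfig, build_stimulus_set, load_trajectory, save_trajectory

RESULTS = Path(__file__).resolve().parents[1] / "results"
E_VALUES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


def main() -> None:
    outdir = RESULTS / "stimuli"
    outdir.mkdir(parents=True, exist_ok=True)
    trajectories = {
        E: load_trajectory(RESULTS / "trajectories" / f"cycle_E{E:g}.csv")[0]
        for E in E_VALUES
    }
    rows = []
    for experiment in (1, 2):
        cfg = StimulusSetConfig(experiment=experiment)
        stimuli = build_stimulus_set(cfg, trajectories=trajectories)
        for stim in stimuli:
            name = f"exp{experiment}_E{stim.E:g}_{stim.condition}.csv"
            save_trajectory(stim.traj, outdir / name, stim.profile)
            rows.append(
                {
                    "experiment": experiment,
                    "E": stim.E,
                    "condition": stim.condition,
                    "duration_s": stim.profile.duration,
                    "display_loops": stim.display_loops,
                    "file": name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    print(manifest.to_string(index=False))
    print(f"wrote {len(manifest)} stimuli to {outdir}")


if __name__ == "__main__":
    main()
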