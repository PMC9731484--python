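#!/usr/bin/env python
"""Stage 1: simulate the steady movement cycle at each elbow stiffness.

Integrates the two-link arm under the impedance controller for
E in {0, 10, 20, 30, 40, 50} N*m/rad and writes one closed steady cycle per
stiffness to results/trajectories/, plus a console summary of how each cycle
settled.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from stiffsim import (
    ArmParameters,
    ControllerParameters,
    path_geometry,
    save_trajectory,
    simulate_steady_cycle,
)

E_VALUES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
OUTDIR = Path(__file__).resolve().parents[1] / "results" / "trajectories"


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    arm = ArmParameters()
    base = ControllerParameters()
    print(f"{'E (N*m/rad)':>12} {'transients':>10} {'arc length (m)':>15}")
    for E in E_VALUES:
        traj = simulate_steady_cycle(arm, base.with_elbow_stiffness(E))
        geom = path_geometry(traj.x)
        save_trajectory(traj, OUTDIR / f"cycle_E{E:g}.csv")
        print(
            f"{E:>12g} {traj.meta['transient_cycles']:>10d} "
            f"{geom.total_length:>15.4f}"
        )
    print(f"wrote {len(E_VALUES)} steady cycles to {OUTDIR}")


if __name__ == "__main__":
    main()
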