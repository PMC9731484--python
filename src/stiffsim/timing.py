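"""Arc-length geometry of closed sampled paths and velocity-profile retiming.

The perceptual stimuli are one steady cycle of the simulated endpoint path
shown under four timing conditions:

* ``original`` — the time course produced by the dynamics itself;
* ``constant`` — constant tangential speed (0.185 m/s for every path);
* ``inverse``  — speed follows v(t) = K * R(t)^(-1/3), the *inverse* of the
  empirical one-third power law (fast where the path curves sharply), with K
  tuned so each path keeps its constant-condition period;
* ``variable`` — the constant-condition time vector of the stiffest path
  (E = 50 N*m/rad) transplanted sample-for-sample onto every path, breaking
  any speed-curvature power law.

Retiming never touches positions: it only assigns new, strictly increasing
time stamps to the same samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    ArmParameters,
    ControllerParameters,
    StateTrajectory,
    simulate_steady_cycle,
)

__all__ = [
    "PathGeometry",
    "TimingProfile",
    "Stimulus",
    "StimulusSetConfig",
    "path_geometry",
    "retime_constant",
    "retime_inverse",
    "retime_variable",
    "build_stimulus_set",
]

CONDITIONS = ("original", "constant", "inverse", "variable")


@dataclass(frozen=True)
class PathGeometry:
    """Cumulative arc length and radius of curvature of a closed sampled path."""

    s: np.ndarray
    R: np.ndarray
    total_length: float
    closed_duplicate: bool  # last sample re-visits the first


@dataclass(frozen=True)
class TimingProfile:
    """New time stamps for an existing path under one timing condition."""

    condition: str
    t_new: np.ndarray
    v_target: float | None = None
    K_gain: float | None = None
    source_E: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        t = np.asarray(self.t_new, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_new must be strictly increasing")
        object.__setattr__(self, "t_new", t)

    @property
    def duration(self) -> float:
        return float(self.t_new[-1] - self.t_new[0])


@dataclass
class Stimulus:
    """One displayed arm motion: a path plus a timing profile."""

    traj: StateTrajectory
    profile: TimingProfile
    E: float
    condition: str
    display_loops: int = 1


def _positions(traj) -> np.ndarray:
    if isinstance(traj, StateTrajectory):
        return traj.x
    return np.asarray(traj, dtype=float)


def _detect_closing_duplicate(x: np.ndarray) -> bool:
    chords = np.linalg.norm(np.diff(x, axis=0), axis=1)
    gap = np.linalg.norm(x[-1] - x[0])
    return bool(gap < 0.5 * np.median(chords))


def _circular_smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    pad = window // 2
    ext = np.concatenate([y[-pad:], y, y[:pad]])
    return np.convolve(ext, kernel, mode="valid")


def _periodic_deriv5(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fourth-order centered first and second derivatives w.r.t. sample index."""
    yp1, yp2 = np.roll(y, -1), np.roll(y, -2)
    ym1, ym2 = np.roll(y, 1), np.roll(y, 2)
    d1 = (-yp2 + 8 * yp1 - 8 * ym1 + ym2) / 12.0
    d2 = (-yp2 + 16 * yp1 - 30 * y + 16 * ym1 - ym2) / 12.0
    return d1, d2


def path_geometry(
    traj,
    r_max: float = 10.0,
    smooth_window: int = 9,
) -> PathGeometry:
    """Arc length and radius of curvature of a closed path.

    Arc length accumulates chord lengths; the total includes the closing
    chord back to the first sample. Curvature uses kappa = |v x a| / |v|^3
    with v, a obtained by fourth-order periodic finite differences of the
    lightly smoothed coordinates with respect to sample index (the formula is
    invariant to the parameterization, so index spacing is immaterial). R is
    capped at ``r_max``; a final sample that duplicates the first is detected
    and handled so the wrap never differences near-coincident points.
    """
    x = _positions(traj)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("path must be an (N, 2) array of positions")
    if x.shape[0] < 8:
        raise ValueError("need at least 8 samples")

    dup = _detect_closing_duplicate(x)
    loop = x[:-1] if dup else x

    chords = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    closing = np.linalg.norm(loop[0] - loop[-1])
    total = float(chords.sum() + closing)
    if total <= 0:
        raise ValueError("zero-length path")
    s_loop = np.concatenate([[0.0], np.cumsum(chords)])

    xs = _circular_smooth(loop[:, 0], smooth_window)
    ys = _circular_smooth(loop[:, 1], smooth_window)
    vx, ax = _periodic_deriv5(xs)
    vy, ay = _periodic_deriv5(ys)
    speed3 = (vx**2 + vy**2) ** 1.5
    cross = np.abs(vx * ay - vy * ax)
    with np.errstate(divide="ignore", invalid="ignore"):
        R_loop = np.where(cross > 0, speed3 / cross, np.inf)
    R_loop = np.clip(np.nan_to_num(R_loop, nan=r_max, posinf=r_max), None, r_max)
    R_loop = np.maximum(R_loop, np.finfo(float).tiny)

    if dup:
        s = np.concatenate([s_loop, [total]])
        R = np.concatenate([R_loop, [R_loop[0]]])
    else:
        s, R = s_loop, R_loop
    return PathGeometry(s=s, R=R, total_length=total, closed_duplicate=dup)


def retime_constant(traj, geom: PathGeometry, v: float = 0.185) -> TimingProfile:
    """Assign times so the endpoint traverses the path at constant speed v."""
    if v <= 0:
        raise ValueError("v must be positive")
    return TimingProfile(condition="constant", t_new=geom.s / v, v_target=float(v))


def retime_inverse(traj, geom: PathGeometry, target_duration: float) -> TimingProfile:
    """Assign times so speed follows v = K * R^(-1/3) with the period matched.

    The duration of the profile is T(K) = (1/K) * sum ds * R^(1/3), exactly
    proportional to 1/K, so the gain matching ``target_duration`` has the
    closed form K = sum(ds * R^(1/3)) / target_duration.
    """
    if target_duration <= 0:
        raise ValueError("target_duration must be positive")
    ds = np.diff(geom.s)
    if np.any(~np.isfinite(geom.R)) or np.all(ds == 0):
        raise ValueError("degenerate geometry")
    R13 = geom.R ** (1.0 / 3.0)
    # midpoint value of R^(1/3) on each segment
    seg = 0.5 * (R13[:-1] + R13[1:])
    weight = float(np.sum(ds * seg))
    if not np.isfinite(weight) or weight <= 0:
        raise ValueError("degenerate radius-of-curvature profile")
    K = weight / target_duration
    t_new = np.concatenate([[0.0], np.cumsum(ds * seg / K)])
    return TimingProfile(condition="inverse", t_new=t_new, K_gain=K)


def retime_variable(traj, donor_profile: TimingProfile) -> TimingProfile:
    """Transplant the donor's time vector verbatim onto this path's samples."""
    n = len(_positions(traj))
    if donor_profile.t_new.size != n:
        raise ValueError(
            f"sample-count mismatch: path has {n}, donor has {donor_profile.t_new.size}"
        )
    return TimingProfile(
        condition="variable",
        t_new=donor_profile.t_new.copy(),
        source_E=donor_profile.source_E,
    )


def original_profile(traj: StateTrajectory) -> TimingProfile:
    """The veridical timing: the dynamics' own time stamps."""
    return TimingProfile(condition="original", t_new=traj.t.copy())


@dataclass(frozen=True)
class StimulusSetConfig:
    """What to simulate and how to retime it."""

    experiment: int = 1
    E_values: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    conditions: tuple[str, ...] = CONDITIONS
    exp2_E: float = 30.0
    donor_E: float = 50.0
    v_constant: float = 0.185
    display_time: float = 20.0

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if not self.E_values:
            raise ValueError("E_values must be nonempty")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad or not self.conditions:
            raise ValueError(f"invalid conditions {bad or self.conditions}")


def build_stimulus_set(
    config: StimulusSetConfig,
    params: ArmParameters | None = None,
    ctrl_base: ControllerParameters | None = None,
    trajectories: dict[float, StateTrajectory] | None = None,
) -> list[Stimulus]:
    """Assemble the full stimulus set for one experiment.

    Experiment 1 crosses every elbow stiffness with every timing condition
    (6 x 4 = 24 stimuli with the defaults); Experiment 2 shows the single
    E = 30 N*m/rad path under all four timing conditions. Pre-simulated
    steady cycles may be passed in ``trajectories`` (keyed by E) to avoid
    re-integration. Each stimulus carries the loop count needed to fill the
    display time.
    """
    params = params or ArmParameters()
    ctrl_base = ctrl_base or ControllerParameters()

    if config.experiment == 1:
        path_Es = list(config.E_values)
    else:
        path_Es = [config.exp2_E]
    needed = sorted(set(path_Es) | {config.donor_E})

    trajectories = dict(trajectories or {})
    for E in needed:
        if E not in trajectories:
            trajectories[E] = simulate_steady_cycle(
                params, ctrl_base.with_elbow_stiffness(E)
            )

    geoms = {E: path_geometry(trajectories[E]) for E in needed}
    donor = retime_constant(
        trajectories[config.donor_E], geoms[config.donor_E], config.v_constant
    )
    donor = TimingProfile(
        condition=donor.condition,
        t_new=donor.t_new,
        v_target=donor.v_target,
        source_E=config.donor_E,
    )

    stimuli: list[Stimulus] = []
    for E in path_Es:
        traj, geom = trajectories[E], geoms[E]
        const = retime_constant(traj, geom, config.v_constant)
        for cond in config.conditions:
            if cond == "original":
                profile = original_profile(traj)
            elif cond == "constant":
                profile = const
            elif cond == "inverse":
                profile = retime_inverse(traj, geom, const.duration)
            else:
                profile = retime_variable(traj, donor)
            loops = max(1, math.ceil(config.display_time / profile.duration))
            stimuli.append(
                Stimulus(
                    traj=traj, profile=profile, E=E, condition=cond,
                    display_loops=loops,
                )
            )
    return stimuli
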