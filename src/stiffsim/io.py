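"""Configuration and file round-trips for the pipeline stages.

Trajectories travel between stages as plain CSV (one row per sample, columns
``t, q1, q2, qd1, qd2, x, y, xd, yd`` plus, for retimed stimuli, ``t_new``
and ``condition``) with a small JSON sidecar recording units. The pipeline
configuration is a YAML mapping mirroring the parameter dataclasses; unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import ArmParameters, ControllerParameters, StateTrajectory
from .subjects import SubjectModel
from .timing import TimingProfile

__all__ = [
    "PipelineConfig",
    "load_config",
    "save_config",
    "save_trajectory",
    "load_trajectory",
]

_UNITS = {
    "t": "s", "q1": "rad", "q2": "rad", "qd1": "rad/s", "qd2": "rad/s",
    "x": "m", "y": "m", "xd": "m/s", "yd": "m/s", "t_new": "s", "condition": "",
}

TRAJECTORY_COLUMNS = ("t", "q1", "q2", "qd1", "qd2", "x", "y", "xd", "yd")


def save_trajectory(
    traj: StateTrajectory,
    path: str | Path,
    profile: TimingProfile | None = None,
) -> None:
    """Write a trajectory (optionally with its retimed time vector) to CSV."""
    path = Path(path)
    data = {
        "t": traj.t,
        "q1": traj.q[:, 0], "q2": traj.q[:, 1],
        "qd1": traj.qdot[:, 0], "qd2": traj.qdot[:, 1],
        "x": traj.x[:, 0], "y": traj.x[:, 1],
        "xd": traj.xdot[:, 0], "yd": traj.xdot[:, 1],
    }
    if profile is not None:
        data["t_new"] = profile.t_new
        data["condition"] = [profile.condition] * len(traj)
    df = pd.DataFrame(data)
    # %.17g is the shortest format guaranteed to round-trip IEEE doubles
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = {c: _UNITS[c] for c in df.columns}
    sidecar["meta"] = {
        k: v for k, v in traj.meta.items() if isinstance(v, (int, float, str, bool))
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_trajectory(path: str | Path):
    """Read a trajectory CSV back; returns (StateTrajectory, TimingProfile | None).

    Validates the schema and that both time columns are strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("meta", {})
    traj = StateTrajectory(
        t=t,
        q=df[["q1", "q2"]].to_numpy(dtype=float),
        qdot=df[["qd1", "qd2"]].to_numpy(dtype=float),
        x=df[["x", "y"]].to_numpy(dtype=float),
        xdot=df[["xd", "yd"]].to_numpy(dtype=float),
        meta=meta,
    )
    profile = None
    if "t_new" in df.columns:
        profile = TimingProfile(
            condition=str(df["condition"].iloc[0]),
            t_new=df["t_new"].to_numpy(dtype=float),
        )
    return traj, profile


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs, in plain data."""

    arm: ArmParameters = field(default_factory=ArmParameters)
    controller: ControllerParameters = field(default_factory=ControllerParameters)
    E_values: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    conditions: tuple[str, ...] = ("original", "constant", "inverse", "variable")
    exp2_E: float = 30.0
    v_constant: float = 0.185
    display_time: float = 20.0
    n_subjects_exp1: int = 10
    n_subjects_exp2: int = 10
    subject_model: SubjectModel = field(default_factory=SubjectModel)
    exp2_temporal_penalty: float = 0.5
    seed: int = 0
    outdir: str = "results"


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    nested = {"arm": ArmParameters, "controller": ControllerParameters,
              "subject_model": SubjectModel}
    for key, value in data.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = _build(nested[key], value, f"{path}.{key}")
        elif key in ("Kx", "Bx"):
            kwargs[key] = np.asarray(value, dtype=float)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return _build(PipelineConfig, data, "config")
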