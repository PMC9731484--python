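"""Path and temporal feature battery for one stimulus cycle.

Path features (centroid, oblongness, enclosed area, mean curvature) depend
only on the endpoint geometry and are therefore identical across the four
timing conditions of one path. Joint features (ranges of motion, shoulder-
elbow relative phase) depend on the joint-angle waveforms. Temporal features
(RMS velocity, acceleration and jerk in joint and endpoint coordinates) are
computed against the stimulus' own — possibly non-uniform — time vector and
are what distinguishes the timing conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dynamics import StateTrajectory
from .timing import PathGeometry, TimingProfile, Stimulus, path_geometry

__all__ = [
    "PathSummary",
    "JointSummary",
    "RmsKinematics",
    "FeatureVector",
    "path_summary",
    "joint_summary",
    "rms_kinematics",
    "feature_vector",
    "feature_table",
]


@dataclass(frozen=True)
class PathSummary:
    centroid: tuple[float, float]
    oblongness: float
    area: float
    mean_curvature: float


@dataclass(frozen=True)
class JointSummary:
    shoulder_rom: float
    elbow_rom: float
    relative_phase: float  # rad in (-pi, pi]; NaN when a joint does not move


@dataclass(frozen=True)
class RmsKinematics:
    rms_joint_vel: tuple[float, float]
    rms_joint_acc: tuple[float, float]
    rms_joint_jerk: tuple[float, float]
    rms_end_vel: tuple[float, float]
    rms_end_acc: tuple[float, float]
    rms_end_jerk: tuple[float, float]
    rms_end_speed: float
    rms_end_acc_mag: float
    rms_end_jerk_mag: float


@dataclass(frozen=True)
class FeatureVector:
    E: float
    condition: str
    centroid_x: float
    centroid_y: float
    oblongness: float
    area: float
    mean_curvature: float
    relative_phase: float
    shoulder_rom: float
    elbow_rom: float
    rms_end_speed: float
    rms_end_acc_mag: float
    rms_end_jerk_mag: float


def _loop_and_weights(x: np.ndarray, weights: str):
    """Strip a closing duplicate and build per-sample quadrature weights."""
    from .timing import _detect_closing_duplicate

    if _detect_closing_duplicate(x):
        x = x[:-1]
    n = x.shape[0]
    if weights == "uniform":
        w = np.full(n, 1.0 / n)
    elif weights == "arclength":
        chords = np.linalg.norm(np.diff(np.vstack([x, x[:1]]), axis=0), axis=1)
        seg = 0.5 * (chords + np.roll(chords, 1))  # half of each adjacent chord
        tot = seg.sum()
        if tot <= 0:
            raise ValueError("zero-length path")
        w = seg / tot
    else:
        raise ValueError("weights must be 'arclength' or 'uniform'")
    return x, w


def path_summary(
    traj,
    geom: PathGeometry | None = None,
    weights: str = "arclength",
) -> PathSummary:
    """Centroid, oblongness, enclosed area and mean curvature of a closed path.

    The centroid and the covariance behind oblongness are arc-length weighted
    by default, which makes them invariant to how densely the path is sampled
    along its course; ``weights='uniform'`` gives the plain per-sample moments.
    Oblongness is the ratio of the larger to the smaller eigenvalue of the 2x2
    position covariance (1 for a circle); the area uses the shoelace formula;
    mean curvature averages 1/R along arc length.
    """
    if isinstance(traj, StateTrajectory):
        x_full = traj.x
    else:
        x_full = np.asarray(traj, dtype=float)
    if geom is None:
        geom = path_geometry(x_full)

    x, w = _loop_and_weights(x_full, weights)
    centroid = w @ x
    dx = x - centroid
    cov = (w[:, None] * dx).T @ dx
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 1e-15 * max(evals[1], 1.0):
        raise ValueError("degenerate path: zero variance in one direction")
    oblongness = float(evals[1] / evals[0])

    area = 0.5 * abs(
        float(np.sum(x[:, 0] * np.roll(x[:, 1], -1) - np.roll(x[:, 0], -1) * x[:, 1]))
    )

    R = geom.R[:-1] if geom.closed_duplicate else geom.R
    ds = np.diff(geom.s)
    if geom.closed_duplicate:
        seg_R = 0.5 * (geom.R[:-1] + geom.R[1:])
        mean_curv = float(np.sum(ds / seg_R) / geom.total_length)
    else:
        # wrap: weight each sample by adjacent half-chords
        chords = np.append(ds, geom.total_length - geom.s[-1])
        wseg = 0.5 * (chords + np.roll(chords, 1))
        mean_curv = float(np.sum(wseg / R) / geom.total_length)

    return PathSummary(
        centroid=(float(centroid[0]), float(centroid[1])),
        oblongness=oblongness,
        area=area,
        mean_curvature=mean_curv,
    )


def _strip_duplicate_cycle(t: np.ndarray, signals: np.ndarray, x: np.ndarray):
    """Return (t, signals) over one open period plus the period length.

    A final sample that re-visits the first endpoint position is treated as
    the closing sample of the cycle and dropped; otherwise the samples are
    assumed to cover one open period and the period is extended by a median
    step.
    """
    from .timing import _detect_closing_duplicate

    if _detect_closing_duplicate(x):
        period = float(t[-1] - t[0])
        return t[:-1], signals[:-1], period
    period = float(t[-1] - t[0] + np.median(np.diff(t)))
    return t, signals, period


def joint_summary(traj: StateTrajectory, profile: TimingProfile | None = None) -> JointSummary:
    """Joint ranges of motion and the shoulder-elbow relative phase.

    The relative phase is found by circular cross-correlation of the
    mean-removed joint-angle waveforms over one cycle, resampled to a uniform
    time grid; the lag of the correlation peak maps to phase as
    2*pi*lag/period, reported in (-pi, pi]. The phase is positive when the
    elbow waveform trails the shoulder waveform. A joint that does not move
    has no defined phase (NaN).
    """
    t = profile.t_new if profile is not None else traj.t
    q = traj.q
    shoulder_rom = float(np.ptp(q[:, 0]))
    elbow_rom = float(np.ptp(q[:, 1]))

    t_open, q_open, period = _strip_duplicate_cycle(t, q, traj.x)
    if np.std(q_open[:, 0]) < 1e-12 or np.std(q_open[:, 1]) < 1e-12:
        return JointSummary(shoulder_rom, elbow_rom, float("nan"))

    n = t_open.size
    tu = t[0] + period * np.arange(n) / n
    # periodic interpolation onto the uniform grid
    tp = np.concatenate([t_open, [t_open[0] + period]])
    q1p = np.concatenate([q_open[:, 0], [q_open[0, 0]]])
    q2p = np.concatenate([q_open[:, 1], [q_open[0, 1]]])
    q1 = np.interp(tu, tp, q1p)
    q2 = np.interp(tu, tp, q2p)
    q1 -= q1.mean()
    q2 -= q2.mean()

    corr = np.fft.irfft(np.conj(np.fft.rfft(q1)) * np.fft.rfft(q2), n=n)
    lag = int(np.argmax(corr))
    if lag > n / 2:
        lag -= n
    phase = 2 * np.pi * lag / n
    if phase <= -np.pi:
        phase += 2 * np.pi
    elif phase > np.pi:
        phase -= 2 * np.pi
    return JointSummary(shoulder_rom, elbow_rom, float(phase))


def _periodic_gradient(y: np.ndarray, t: np.ndarray, period: float, pad: int = 4):
    """d/dt of a periodic signal sampled on a (possibly nonuniform) grid."""
    tp = np.concatenate([t[-pad:] - period, t, t[:pad] + period])
    yp = np.concatenate([y[-pad:], y, y[:pad]])
    return np.gradient(yp, tp)[pad:-pad]


def rms_kinematics(traj: StateTrajectory, profile: TimingProfile | None = None) -> RmsKinematics:
    """Time-weighted RMS velocity, acceleration and jerk over one cycle.

    Derivatives are taken with respect to the stimulus' own time vector by
    second-order finite differences with periodic wrap-around, so nonuniform
    grids (constant/inverse/variable conditions) are handled directly. The RMS
    is the time average over the cycle, computed by the trapezoid rule.
    """
    t = profile.t_new if profile is not None else traj.t
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must have strictly positive steps")
    t_open, pos, period = _strip_duplicate_cycle(
        t, np.column_stack([traj.q, traj.x]), traj.x
    )

    def rms(sig: np.ndarray) -> float:
        # trapezoid over the closed cycle (repeat first sample at t0+T)
        tt = np.concatenate([t_open, [t_open[0] + period]])
        ss = np.concatenate([sig, [sig[0]]])
        return float(np.sqrt(np.trapezoid(ss**2, tt) / period))

    derivs = []
    cur = pos
    for _ in range(3):
        cur = np.column_stack(
            [_periodic_gradient(cur[:, j], t_open, period) for j in range(cur.shape[1])]
        )
        derivs.append(cur)

    out = {}
    names = ["vel", "acc", "jerk"]
    for name, d in zip(names, derivs):
        out[f"rms_joint_{name}"] = (rms(d[:, 0]), rms(d[:, 1]))
        out[f"rms_end_{name}"] = (rms(d[:, 2]), rms(d[:, 3]))
    mags = [np.sqrt(d[:, 2] ** 2 + d[:, 3] ** 2) for d in derivs]
    return RmsKinematics(
        rms_joint_vel=out["rms_joint_vel"],
        rms_joint_acc=out["rms_joint_acc"],
        rms_joint_jerk=out["rms_joint_jerk"],
        rms_end_vel=out["rms_end_vel"],
        rms_end_acc=out["rms_end_acc"],
        rms_end_jerk=out["rms_end_jerk"],
        rms_end_speed=rms(mags[0]),
        rms_end_acc_mag=rms(mags[1]),
        rms_end_jerk_mag=rms(mags[2]),
    )


def feature_vector(stim: Stimulus, geom: PathGeometry | None = None) -> FeatureVector:
    """All features of one stimulus, flattened for the feature table."""
    ps = path_summary(stim.traj, geom)
    js = joint_summary(stim.traj, stim.profile)
    rk = rms_kinematics(stim.traj, stim.profile)
    return FeatureVector(
        E=stim.E,
        condition=stim.condition,
        centroid_x=ps.centroid[0],
        centroid_y=ps.centroid[1],
        oblongness=ps.oblongness,
        area=ps.area,
        mean_curvature=ps.mean_curvature,
        relative_phase=js.relative_phase,
        shoulder_rom=js.shoulder_rom,
        elbow_rom=js.elbow_rom,
        rms_end_speed=rk.rms_end_speed,
        rms_end_acc_mag=rk.rms_end_acc_mag,
        rms_end_jerk_mag=rk.rms_end_jerk_mag,
    )


def feature_table(stimuli) -> "pandas.DataFrame":
    """One row of features per stimulus (E x condition)."""
    import pandas as pd

    geoms: dict[int, object] = {}
    rows = []
    for stim in stimuli:
        key = id(stim.traj)
        if key not in geoms:
            geoms[key] = path_geometry(stim.traj)
        rows.append(asdict(feature_vector(stim, geoms[key])))
    return pd.DataFrame(rows)
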