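"""Rigid-body dynamics of a two-link planar arm under an impedance-primitive controller.

The arm is the classic planar double pendulum driven by joint torques,

    M(q) q'' + C(q, q') q' + g(q) = tau,

with ``q = (q1, q2)`` the shoulder and elbow angles. The controller composes
two dynamic primitives through mechanical impedances: an oscillatory attractor
pulling the endpoint (the "hand") along a circular reference through an
endpoint stiffness/damping pair (Kx, Bx), and a fixed-point attractor pulling
the joints toward a nominal configuration q_r through a joint stiffness Kq
whose only nonzero entry E is the elbow stiffness:

    tau = J(q)^T Kx (x_r - x) - J(q)^T Bx x' + Kq (q_r - q).

Varying E in {0, 10, ..., 50} N*m/rad produces the family of orbital endpoint
paths that serve as perceptual stimuli downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ArmParameters",
    "ControllerParameters",
    "StateTrajectory",
    "SimulationError",
    "forward_kinematics",
    "inverse_kinematics",
    "jacobian",
    "dynamics_terms",
    "reference_endpoint",
    "controller_torque",
    "simulate_steady_cycle",
    "kinetic_energy",
    "potential_energy",
]


class SimulationError(RuntimeError):
    """Raised when the steady-cycle integration cannot satisfy its contract."""


@dataclass(frozen=True)
class ArmParameters:
    """Geometry, inertia and gravity of the two-link arm.

    Defaults approximate the upper arm (link 1) and forearm-plus-hand
    (link 2) of an average adult male, taken from standard anthropometric
    segment tables: lengths ``l_i`` (m), masses ``m_i`` (kg), proximal-joint
    to center-of-mass distances ``lc_i`` (m) and centroidal moments of
    inertia ``I_i`` (kg m^2). Gravity acts in the plane of motion along
    ``g_dir`` (a unit vector; the default is straight down, i.e. a vertical
    plane with the shoulder at the origin).
    """

    l1: float = 0.33
    l2: float = 0.32
    m1: float = 2.10
    m2: float = 1.65
    lc1: float = 0.144
    lc2: float = 0.218
    I1: float = 0.024
    I2: float = 0.037
    g_mag: float = 9.81
    g_dir: tuple[float, float] = (0.0, -1.0)

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "m1", "m2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.lc1 <= self.l1 and 0 < self.lc2 <= self.l2):
            raise ValueError("center-of-mass offsets must satisfy 0 < lc_i <= l_i")
        if self.g_mag < 0:
            raise ValueError("g_mag must be nonnegative")
        if not np.isclose(np.hypot(*self.g_dir), 1.0, atol=1e-9):
            raise ValueError("g_dir must be a unit vector")

    @property
    def gravity_vector(self) -> np.ndarray:
        return self.g_mag * np.asarray(self.g_dir, dtype=float)


def _check_spsd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ValueError(f"{name} must have nonnegative eigenvalues")
    return mat


@dataclass(frozen=True)
class ControllerParameters:
    """Impedance controller parameters and the oscillatory endpoint reference.

    ``E`` is the elbow entry of the joint stiffness matrix
    ``Kq = [[0, 0], [0, E]]``; the shoulder row is zero so the fixed-point
    primitive acts on the elbow alone. The endpoint reference orbits
    ``circle_center`` at radius ``circle_radius`` with angular frequency
    ``omega`` (default: one revolution per 3.33 s).
    """

    Kx: np.ndarray = field(default_factory=lambda: np.diag([500.0, 500.0]))
    Bx: np.ndarray = field(default_factory=lambda: np.diag([10.0, 10.0]))
    E: float = 0.0
    qr: tuple[float, float] = (np.pi / 4, np.pi / 4)
    circle_center: tuple[float, float] = (0.25, 0.25)
    circle_radius: float = 0.1
    omega: float = 2 * np.pi / 3.33
    phase0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "Kx", _check_spsd(self.Kx, "Kx"))
        object.__setattr__(self, "Bx", _check_spsd(self.Bx, "Bx"))
        if self.E < 0:
            raise ValueError("elbow stiffness E must be nonnegative")
        if self.circle_radius <= 0:
            raise ValueError("circle_radius must be positive")
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    @property
    def Kq(self) -> np.ndarray:
        return np.array([[0.0, 0.0], [0.0, self.E]])

    @property
    def period(self) -> float:
        return 2 * np.pi / self.omega

    def with_elbow_stiffness(self, E: float) -> "ControllerParameters":
        return replace(self, E=float(E))


@dataclass
class StateTrajectory:
    """Time-stamped joint states of one cycle with derived endpoint kinematics.

    ``t`` is nominally a 1 ms grid spanning exactly one reference period; the
    final sample closes the loop (it re-samples the orbit one period after the
    first). ``q``/``qdot`` are (N, 2) joint angles and velocities; ``x``/
    ``xdot`` the endpoint position and velocity obtained through the forward
    kinematics and Jacobian.
    """

    t: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    x: np.ndarray
    xdot: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("q", "qdot", "x", "xdot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.t.size, 2):
                raise ValueError(f"{name} must have shape (len(t), 2)")
            setattr(self, name, arr)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @classmethod
    def from_joint_states(
        cls,
        params: ArmParameters,
        t: np.ndarray,
        q: np.ndarray,
        qdot: np.ndarray,
        meta: dict | None = None,
    ) -> "StateTrajectory":
        q = np.asarray(q, dtype=float)
        qdot = np.asarray(qdot, dtype=float)
        x, _ = forward_kinematics(params, q)
        xdot = np.einsum("nij,nj->ni", jacobian(params, q), qdot)
        return cls(t=np.asarray(t, float), q=q, qdot=qdot, x=x, xdot=xdot, meta=meta or {})

    def __len__(self) -> int:
        return self.t.size


def forward_kinematics(params: ArmParameters, q: np.ndarray):
    """Endpoint and elbow positions for joint angles ``q`` (shoulder at origin).

    ``q`` may be a single (2,) configuration or a batch (..., 2); positions
    have the same leading shape.
    """
    q = np.asarray(q, dtype=float)
    q1 = q[..., 0]
    q12 = q[..., 0] + q[..., 1]
    elbow = np.stack([params.l1 * np.cos(q1), params.l1 * np.sin(q1)], axis=-1)
    hand = elbow + np.stack(
        [params.l2 * np.cos(q12), params.l2 * np.sin(q12)], axis=-1
    )
    return hand, elbow


def inverse_kinematics(
    params: ArmParameters, x: np.ndarray, elbow_up: bool = True
) -> np.ndarray:
    """Joint angles reaching endpoint ``x``; the elbow-up branch has q2 >= 0."""
    x = np.asarray(x, dtype=float)
    d2 = float(x @ x)
    l1, l2 = params.l1, params.l2
    c2 = (d2 - l1**2 - l2**2) / (2 * l1 * l2)
    if not -1 - 1e-12 <= c2 <= 1 + 1e-12:
        raise ValueError("endpoint outside the reachable annulus")
    c2 = np.clip(c2, -1.0, 1.0)
    q2 = np.arccos(c2) if elbow_up else -np.arccos(c2)
    q1 = np.arctan2(x[1], x[0]) - np.arctan2(l2 * np.sin(q2), l1 + l2 * np.cos(q2))
    return np.array([q1, q2])


def jacobian(params: ArmParameters, q: np.ndarray) -> np.ndarray:
    """Endpoint Jacobian dx/dq; batched input (..., 2) gives (..., 2, 2)."""
    q = np.asarray(q, dtype=float)
    q1 = q[..., 0]
    q12 = q[..., 0] + q[..., 1]
    l1, l2 = params.l1, params.l2
    s1, c1 = np.sin(q1), np.cos(q1)
    s12, c12 = np.sin(q12), np.cos(q12)
    J = np.empty(q.shape[:-1] + (2, 2))
    J[..., 0, 0] = -l1 * s1 - l2 * s12
    J[..., 0, 1] = -l2 * s12
    J[..., 1, 0] = l1 * c1 + l2 * c12
    J[..., 1, 1] = l2 * c12
    return J


def dynamics_terms(params: ArmParameters, q: np.ndarray, qdot: np.ndarray):
    """Inertia matrix M(q), Coriolis matrix C(q, q') and gravity torque g(q).

    C uses the Christoffel-symbol form, so ``dM/dt - 2C`` is skew-symmetric;
    the gravity torque is the configuration gradient of the gravitational
    potential with gravity ``g_mag * g_dir`` acting on both link centers of
    mass.
    """
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    l1, lc1, lc2 = params.l1, params.lc1, params.lc2
    m1, m2, I1, I2 = params.m1, params.m2, params.I1, params.I2
    c2 = np.cos(q[1])
    s2 = np.sin(q[1])

    a = I1 + I2 + m1 * lc1**2 + m2 * (l1**2 + lc2**2)
    b = m2 * l1 * lc2
    d = I2 + m2 * lc2**2
    M = np.array(
        [
            [a + 2 * b * c2, d + b * c2],
            [d + b * c2, d],
        ]
    )
    h = b * s2
    C = np.array(
        [
            [-h * qdot[1], -h * (qdot[0] + qdot[1])],
            [h * qdot[0], 0.0],
        ]
    )
    # g(q) = -d/dq [ sum_i m_i g_vec . p_ci ]
    gx, gy = params.gravity_vector
    q1 = q[0]
    q12 = q[0] + q[1]
    # p_c1 = lc1*(c1, s1); p_c2 = l1*(c1, s1) + lc2*(c12, s12)
    dU1 = -(m1 * lc1 + m2 * l1) * (-gx * np.sin(q1) + gy * np.cos(q1)) - m2 * lc2 * (
        -gx * np.sin(q12) + gy * np.cos(q12)
    )
    dU2 = -m2 * lc2 * (-gx * np.sin(q12) + gy * np.cos(q12))
    g_tau = np.array([dU1, dU2])
    return M, C, g_tau


def kinetic_energy(params: ArmParameters, q: np.ndarray, qdot: np.ndarray) -> float:
    M, _, _ = dynamics_terms(params, q, qdot)
    return 0.5 * float(qdot @ M @ qdot)


def potential_energy(params: ArmParameters, q: np.ndarray) -> float:
    """Gravitational potential; zero when both centers of mass sit at the shoulder."""
    g_vec = params.gravity_vector
    q = np.asarray(q, dtype=float)
    c1 = params.lc1 * np.array([np.cos(q[0]), np.sin(q[0])])
    c2 = params.l1 * np.array([np.cos(q[0]), np.sin(q[0])]) + params.lc2 * np.array(
        [np.cos(q[0] + q[1]), np.sin(q[0] + q[1])]
    )
    return -float(params.m1 * g_vec @ c1 + params.m2 * g_vec @ c2)


def reference_endpoint(ctrl: ControllerParameters, t):
    """Reference endpoint position and velocity on the circular orbit at time t."""
    t = np.asarray(t, dtype=float)
    ang = ctrl.omega * t + ctrl.phase0
    r = ctrl.circle_radius
    center = np.asarray(ctrl.circle_center, dtype=float)
    xr = center + r * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    xrdot = r * ctrl.omega * np.stack([-np.sin(ang), np.cos(ang)], axis=-1)
    return xr, xrdot


def controller_torque(
    ctrl: ControllerParameters,
    params: ArmParameters,
    t: float,
    q: np.ndarray,
    qdot: np.ndarray,
) -> np.ndarray:
    """tau = J^T Kx (xr - x) - J^T Bx x' + Kq (qr - q)."""
    q = np.asarray(q, dtype=float)
    qdot = np.asarray(qdot, dtype=float)
    x, _ = forward_kinematics(params, q)
    J = jacobian(params, q)
    xdot = J @ qdot
    xr, _ = reference_endpoint(ctrl, t)
    qr = np.asarray(ctrl.qr, dtype=float)
    return J.T @ (ctrl.Kx @ (xr - x)) - J.T @ (ctrl.Bx @ xdot) + ctrl.Kq @ (qr - q)


def _rhs(t, y, params, ctrl):
    q = y[:2]
    qdot = y[2:]
    M, C, g_tau = dynamics_terms(params, q, qdot)
    tau = controller_torque(ctrl, params, t, q, qdot)
    qdd = np.linalg.solve(M, tau - C @ qdot - g_tau)
    return np.concatenate([qdot, qdd])


def simulate_steady_cycle(
    params: ArmParameters,
    ctrl: ControllerParameters,
    seed_state: np.ndarray | None = None,
    dt_out: float = 1e-3,
    max_cycles: int = 20,
    min_cycles: int = 0,
    settle_tol: float = 1e-4,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StateTrajectory:
    """Integrate to the steady orbit and return exactly one closed cycle.

    Starts from rest at the elbow-up configuration reaching the reference's
    initial point (or from ``seed_state = [q1, q2, qd1, qd2]``), integrates
    period by period with an adaptive Runge-Kutta scheme, and discards
    transient cycles until the endpoint path of a cycle matches its
    predecessor to within ``settle_tol`` (max distance over corresponding
    samples). The returned cycle spans one full period on a ``dt_out`` grid
    including both endpoints, so its first and last samples coincide up to
    the settle tolerance.
    """
    center = np.asarray(ctrl.circle_center, dtype=float)
    reach = np.hypot(*center) + ctrl.circle_radius
    inner = np.hypot(*center) - ctrl.circle_radius
    if reach > params.l1 + params.l2 or inner < abs(params.l1 - params.l2):
        raise ValueError("reference circle leaves the arm's reachable annulus")

    if seed_state is None:
        xr0, _ = reference_endpoint(ctrl, 0.0)
        q0 = inverse_kinematics(params, xr0, elbow_up=True)
        y = np.concatenate([q0, [0.0, 0.0]])
    else:
        y = np.asarray(seed_state, dtype=float).copy()

    T = ctrl.period
    n_out = int(round(T / dt_out)) + 1
    tau_grid = np.arange(n_out) * dt_out

    prev_x = None
    residual = np.inf
    for cycle in range(max_cycles):
        t0 = cycle * T
        sol = solve_ivp(
            _rhs,
            (t0, t0 + T),
            y,
            args=(params, ctrl),
            method="RK45",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise SimulationError(f"integration failed in cycle {cycle}: {sol.message}")
        ys = sol.sol(t0 + tau_grid)
        q = ys[:2].T
        qdot = ys[2:].T
        x, _ = forward_kinematics(params, q)
        if prev_x is not None:
            residual = float(np.max(np.linalg.norm(x - prev_x, axis=1)))
            if residual < settle_tol and cycle >= min_cycles:
                traj = StateTrajectory.from_joint_states(
                    params,
                    tau_grid,
                    q,
                    qdot,
                    meta={
                        "E": ctrl.E,
                        "condition": "original",
                        "transient_cycles": cycle,
                        "cycle_residual": residual,
                        "closure_error": float(np.linalg.norm(x[-1] - x[0])),
                    },
                )
                return traj
        prev_x = x
        y = ys[:, -1]

    raise SimulationError(
        f"no steady cycle within {max_cycles} cycles (E={ctrl.E}); "
        f"last cycle-to-cycle residual {residual:.3e} m"
    )
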