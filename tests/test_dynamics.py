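import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stiffsim import (
    ArmParameters,
    ControllerParameters,
    SimulationError,
    controller_torque,
    dynamics_terms,
    forward_kinematics,
    inverse_kinematics,
    jacobian,
    reference_endpoint,
    simulate_steady_cycle,
)
from stiffsim.dynamics import _rhs, kinetic_energy, potential_energy

SYM = ArmParameters(l1=0.3, l2=0.3, lc1=0.15, lc2=0.15)
angles = st.floats(-np.pi, np.pi, allow_nan=False)
rates = st.floats(-5.0, 5.0, allow_nan=False)


@pytest.mark.parametrize(
    "params, q, expected",
    [
        (SYM, (0.0, 0.0), (0.6, 0.0)),
        (SYM, (np.pi / 2, np.pi / 2), (-0.3, 0.3)),
        (ArmParameters(), (np.pi / 4, np.pi / 4), (0.33 * np.cos(np.pi / 4),
                                                   0.33 * np.sin(np.pi / 4) + 0.32)),
    ],
)
def test_forward_kinematics_examples(params, q, expected):
    hand, _ = forward_kinematics(params, np.array(q))
    np.testing.assert_allclose(hand, expected, atol=1e-12)


def test_forward_kinematics_default_endpoint_value():
    """Hand evaluation of the FK formula at the nominal joint configuration."""
    hand, _ = forward_kinematics(ArmParameters(), np.array([np.pi / 4, np.pi / 4]))
    np.testing.assert_allclose(hand, [0.233345, 0.553345], atol=5e-6)


def test_inverse_kinematics_round_trip(arm):
    rng = np.random.default_rng(0)
    for _ in range(20):
        q = rng.uniform([-1.0, 0.1], [1.5, 2.8])
        x, _ = forward_kinematics(arm, q)
        np.testing.assert_allclose(inverse_kinematics(arm, x), q, atol=1e-10)
    with pytest.raises(ValueError):
        inverse_kinematics(arm, np.array([1.0, 1.0]))


@given(q1=angles, q2=angles)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_jacobian_matches_finite_difference(q1, q2):
    q = np.array([q1, q2])
    J = jacobian(SYM, q)
    h = 1e-6
    for j in range(2):
        dq = np.zeros(2)
        dq[j] = h
        fd = (forward_kinematics(SYM, q + dq)[0] - forward_kinematics(SYM, q - dq)[0]) / (2 * h)
        np.testing.assert_allclose(J[:, j], fd, atol=1e-8)
    assert np.isclose(np.linalg.det(J), SYM.l1 * SYM.l2 * np.sin(q2), atol=1e-12)


def test_jacobian_examples():
    np.testing.assert_allclose(
        jacobian(SYM, np.array([0.0, 0.0])), [[0.0, 0.0], [0.6, 0.3]], atol=1e-12
    )
    J = jacobian(SYM, np.array([0.3, np.pi / 2]))
    assert np.isclose(np.linalg.det(J), 0.09)


def test_inertia_matrix_positive_definite_and_closed_form(arm):
    rng = np.random.default_rng(1)
    for _ in range(50):
        q = rng.uniform(-np.pi, np.pi, 2)
        M, _, _ = dynamics_terms(arm, q, np.zeros(2))
        assert np.allclose(M, M.T)
        assert np.linalg.eigvalsh(M).min() > 0
    M, _, _ = dynamics_terms(arm, np.array([0.3, np.pi / 2]), np.zeros(2))
    assert np.isclose(M[0, 1], arm.I2 + arm.m2 * arm.lc2**2)


def test_coriolis_vanishes_at_rest(arm):
    _, C, _ = dynamics_terms(arm, np.array([0.4, 1.1]), np.zeros(2))
    np.testing.assert_allclose(C @ np.zeros(2), 0.0)


@given(q1=angles, q2=angles, qd1=rates, qd2=rates)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_coriolis_skew_symmetry(q1, q2, qd1, qd2):
    """dM/dt - 2C must be skew-symmetric (passivity of the rigid-body terms)."""
    q = np.array([q1, q2])
    qd = np.array([qd1, qd2])
    _, C, _ = dynamics_terms(SYM, q, qd)
    h = 1e-7
    Mp, _, _ = dynamics_terms(SYM, q + h * qd, qd)
    Mm, _, _ = dynamics_terms(SYM, q - h * qd, qd)
    Mdot = (Mp - Mm) / (2 * h)
    S = Mdot - 2 * C
    assert np.linalg.norm(S + S.T) < 1e-8


def test_gravity_torque_is_potential_gradient(arm):
    rng = np.random.default_rng(2)
    h = 1e-7
    for _ in range(20):
        q = rng.uniform(-np.pi, np.pi, 2)
        _, _, g_tau = dynamics_terms(arm, q, np.zeros(2))
        for j in range(2):
            dq = np.zeros(2)
            dq[j] = h
            fd = (potential_energy(arm, q + dq) - potential_energy(arm, q - dq)) / (2 * h)
            assert np.isclose(g_tau[j], fd, atol=1e-6)


def test_gravity_off_zeroes_torque():
    p = ArmParameters(g_mag=0.0)
    _, _, g_tau = dynamics_terms(p, np.array([0.7, 0.9]), np.zeros(2))
    np.testing.assert_allclose(g_tau, 0.0)


def test_reference_endpoint_orbit(controller):
    xr, _ = reference_endpoint(controller, 0.0)
    np.testing.assert_allclose(
        xr, np.array(controller.circle_center) + [controller.circle_radius, 0.0]
    )
    xr_q, _ = reference_endpoint(controller, controller.period / 4)
    np.testing.assert_allclose(
        xr_q, np.array(controller.circle_center) + [0.0, controller.circle_radius],
        atol=1e-12,
    )
    t = np.linspace(0, 10, 200)
    _, xrdot = reference_endpoint(controller, t)
    np.testing.assert_allclose(
        np.linalg.norm(xrdot, axis=1),
        controller.circle_radius * controller.omega,
        rtol=1e-12,
    )
    assert np.isclose(controller.circle_radius * controller.omega, 0.1886, atol=5e-4)


def test_controller_torque_zero_cases(arm):
    ctrl = ControllerParameters(E=0.0)
    # place the arm exactly on the reference with zero velocity
    xr, _ = reference_endpoint(ctrl, 0.0)
    q = inverse_kinematics(arm, xr)
    tau = controller_torque(ctrl, arm, 0.0, q, np.zeros(2))
    np.testing.assert_allclose(tau, 0.0, atol=1e-10)
    # with E = 0 the joint reference is irrelevant even though q != qr
    assert not np.allclose(q, ctrl.qr)


def test_controller_torque_matches_brute_force(arm):
    ctrl = ControllerParameters(E=37.0)
    rng = np.random.default_rng(3)
    for _ in range(20):
        t = rng.uniform(0, 5)
        q = rng.uniform(-1, 2, 2)
        qd = rng.uniform(-3, 3, 2)
        # term-by-term re-evaluation of the printed control law
        x, _ = forward_kinematics(arm, q)
        J = jacobian(arm, q)
        xr, _ = reference_endpoint(ctrl, t)
        expected = (
            J.T @ ctrl.Kx @ (xr - x)
            - J.T @ ctrl.Bx @ (J @ qd)
            + np.array([[0.0, 0.0], [0.0, 37.0]]) @ (np.array(ctrl.qr) - q)
        )
        np.testing.assert_allclose(
            controller_torque(ctrl, arm, t, q, qd), expected, atol=1e-12
        )


def test_static_reference_is_fixed_point():
    """With a (nearly) frozen reference and no gravity the endpoint settles on it."""
    from scipy.integrate import solve_ivp

    p = ArmParameters(g_mag=0.0)
    ctrl = ControllerParameters(E=0.0, omega=1e-9)
    xr0, _ = reference_endpoint(ctrl, 0.0)
    q0 = inverse_kinematics(p, xr0) + np.array([0.15, -0.2])
    sol = solve_ivp(_rhs, (0, 25.0), np.concatenate([q0, [0, 0]]),
                    args=(p, ctrl), rtol=1e-8, atol=1e-10)
    x_end, _ = forward_kinematics(p, sol.y[:2, -1])
    np.testing.assert_allclose(x_end, xr0, atol=1e-5)


def test_steady_cycle_is_a_closed_near_circle(traj_family):
    traj = traj_family[0.0]
    assert traj.meta["transient_cycles"] >= 1
    # 1 ms output grid spanning one period
    np.testing.assert_allclose(np.diff(traj.t), 1e-3, atol=1e-12)
    assert np.isclose(traj.t[-1], ControllerParameters().period, atol=1e-3)
    # closed orbit
    assert np.linalg.norm(traj.x[-1] - traj.x[0]) < 1e-4
    # near-circular orbit of radius ~0.1 m around its own centroid
    centroid = traj.x[:-1].mean(axis=0)
    radii = np.linalg.norm(traj.x[:-1] - centroid, axis=1)
    assert 0.09 < radii.mean() < 0.11


def test_endpoint_velocity_consistent_with_jacobian(traj_family, arm):
    traj = traj_family[30.0]
    xdot = np.einsum("nij,nj->ni", jacobian(arm, traj.q), traj.qdot)
    assert np.max(np.linalg.norm(traj.xdot - xdot, axis=1)) < 1e-9


def test_stiffer_elbow_pulls_centroid_toward_joint_reference(traj_family, arm, controller):
    qr_end, _ = forward_kinematics(arm, np.array(controller.qr))
    c0 = traj_family[0.0].x[:-1].mean(axis=0)
    c50 = traj_family[50.0].x[:-1].mean(axis=0)
    pull = qr_end - c0
    shift = c50 - c0
    assert shift @ pull > 0  # displaced toward the joint-reference endpoint
    assert np.linalg.norm(shift) > 0.01


def test_energy_audit_over_one_cycle(traj_family, arm, controller):
    """Work-energy balance: stored-energy change equals boundary work minus dissipation."""
    traj = traj_family[20.0]
    ctrl = controller.with_elbow_stiffness(20.0)
    xr, xrdot = reference_endpoint(ctrl, traj.t)
    qr = np.asarray(ctrl.qr)

    def total_energy(i):
        q, qd = traj.q[i], traj.qdot[i]
        e = kinetic_energy(arm, q, qd) + potential_energy(arm, q)
        err = xr[i] - traj.x[i]
        e += 0.5 * err @ ctrl.Kx @ err
        dq = qr - q
        e += 0.5 * dq @ ctrl.Kq @ dq
        return e

    dissipated = np.trapezoid(
        np.einsum("ni,ij,nj->n", traj.xdot, ctrl.Bx, traj.xdot), traj.t
    )
    injected = np.trapezoid(
        np.einsum("ni,ij,nj->n", xrdot, ctrl.Kx, xr - traj.x), traj.t
    )
    delta = total_energy(len(traj) - 1) - total_energy(0)
    assert abs(delta - (injected - dissipated)) < 0.005 * dissipated


def test_steady_cycle_independent_of_transient_cap(arm, controller, traj_family):
    longer = simulate_steady_cycle(
        arm, controller.with_elbow_stiffness(0.0), min_cycles=traj_family[0.0].meta["transient_cycles"] + 5
    )
    gap = np.max(np.linalg.norm(longer.x - traj_family[0.0].x, axis=1))
    assert gap < 1e-4


def test_unreachable_reference_rejected(arm):
    with pytest.raises(ValueError, match="reachable"):
        simulate_steady_cycle(arm, ControllerParameters(circle_center=(0.6, 0.3)))


def test_nonconvergence_reports_failure(arm, controller):
    with pytest.raises(SimulationError, match="steady cycle"):
        simulate_steady_cycle(arm, controller, max_cycles=2, settle_tol=1e-12)
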