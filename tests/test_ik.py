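"""Jacobian structure, pseudo-inverse solving, integration and closed-loop tracking."""

import numpy as np
import pytest

from dqkin import arm as A
from dqkin import entities as E
from dqkin import ik as K
from dqkin.errors import DivergenceError, UsageError
from dqkin.fixtures import Trajectory
from dqkin.protocols import simulate_reach, straight_reach, twolink_pose_for_point
from dqkin.rigid import RotationSpec, make_rotation

from conftest import random_axis


def random_twolink(rng, theta_range=(0.3, 2.6)):
    return A.TwoLinkArm(
        30, 30,
        make_rotation(RotationSpec(random_axis(rng), rng.uniform(-2, 2))),
        make_rotation(RotationSpec(A.N_ELBOW, rng.uniform(*theta_range))),
    )


class TestJacobianStructure:
    def test_cross_matrix(self, rng):
        a = rng.normal(size=3)
        m = K.cross_matrix(a)
        assert np.allclose(m + m.T, 0.0)
        b = rng.normal(size=3)
        assert np.allclose(m @ b, np.cross(a, b))
        assert K.JacobianBundle.from_matrix(m).rank == 2

    def test_rotation_matrix_matches_sandwich(self, rng):
        from scipy.spatial.transform import Rotation

        spec = RotationSpec(random_axis(rng), rng.uniform(-3, 3))
        m = K.rotation_matrix(make_rotation(spec))
        assert np.allclose(m, Rotation.from_rotvec(spec.angle * spec.axis).as_matrix(), atol=1e-12)

    def test_planar_rank_drops_when_aligned(self):
        assert K.planar_jacobian(A.TwoLinkArm.from_angles(0.7, 0.0)).rank == 1
        assert K.planar_jacobian(A.TwoLinkArm.from_angles(0.7, np.pi)).rank == 1
        assert K.planar_jacobian(A.TwoLinkArm.from_angles(0.7, np.pi / 2)).rank == 2

    def test_planar_jacobian_matches_fk_velocity(self, rng):
        n = A.N_ELBOW
        for _ in range(10):
            arm = A.TwoLinkArm.from_angles(rng.uniform(-2, 2), rng.uniform(0.3, 2.6))
            jb = K.planar_jacobian(arm)
            rates = rng.normal(size=2)
            v3 = A.twolink_fk_velocity(arm, rates[0] * n, rates[1] * n)
            basis = K._plane_basis(n)
            assert np.allclose(jb.j @ rates, basis @ v3, atol=1e-9)

    def test_spatial_jacobian_matches_fk_velocity(self, rng):
        for _ in range(100):
            arm = random_twolink(rng)
            om = rng.normal(size=6)
            jb = K.spatial_jacobian(arm)
            assert np.allclose(jb.j @ om, A.twolink_fk_velocity(arm, om[:3], om[3:]), atol=1e-9)

    def test_constrained_rank_five_generic(self, rng):
        for _ in range(10):
            arm = random_twolink(rng)
            assert K.constrained_jacobian(arm).rank == 5

    def test_constrained_rank_drops_when_aligned(self, rng):
        arm = A.TwoLinkArm(
            30, 30,
            make_rotation(RotationSpec(random_axis(rng), 1.1)),
            make_rotation(RotationSpec(A.N_ELBOW, 0.0)),
        )
        assert K.constrained_jacobian(arm).rank < 5

    def test_kernel_is_self_rotation_about_hand_axis(self, rng):
        # rotating the whole arm about the shoulder–end-effector axis moves nothing
        arm = random_twolink(rng)
        p = E.decode_point(A.twolink_fk_position(arm))
        x = np.concatenate([p / np.linalg.norm(p), np.zeros(3)])
        jb = K.constrained_jacobian(arm)
        assert np.linalg.norm(jb.j @ x) < 1e-9
        # and the nullspace projector keeps it
        assert np.allclose(jb.nullspace @ x, x, atol=1e-9)

    def test_penrose_conditions(self, rng):
        for _ in range(5):
            arm = random_twolink(rng)
            jb = K.constrained_jacobian(arm)
            assert np.allclose(jb.j @ jb.j_plus @ jb.j, jb.j, atol=1e-9)
            assert np.allclose(jb.j_plus @ jb.j @ jb.j_plus, jb.j_plus, atol=1e-9)


class TestSolve:
    def test_zero_rhs(self, rng):
        jb = K.constrained_jacobian(random_twolink(rng))
        assert np.allclose(K.solve_joint_rates(jb, np.zeros(6)), 0.0)

    def test_invertible_planar_direct_inverse(self, rng):
        arm = A.TwoLinkArm.from_angles(0.4, np.pi / 2)
        jb = K.planar_jacobian(arm)
        rhs = rng.normal(size=2)
        assert np.allclose(K.solve_joint_rates(jb, rhs), np.linalg.solve(jb.j, rhs), atol=1e-9)

    def test_minimal_norm_solution(self, rng):
        arm = random_twolink(rng)
        jb = K.constrained_jacobian(arm)
        rhs = np.concatenate([rng.normal(size=3), np.zeros(3)])
        x = K.solve_joint_rates(jb, rhs)
        for _ in range(100):
            z = rng.normal(size=6)
            alt = x + jb.nullspace @ z
            assert np.linalg.norm(x) <= np.linalg.norm(alt) + 1e-12
            # all nullspace-shifted solutions achieve the same residual
            assert np.linalg.norm(jb.j @ alt - rhs) == pytest.approx(np.linalg.norm(jb.j @ x - rhs), abs=1e-9)

    def test_joint_rate_round_trip(self, rng):
        arm = random_twolink(rng)
        jb = K.constrained_jacobian(arm)
        v = rng.normal(size=3)
        x = K.solve_joint_rates(jb, np.concatenate([v, np.zeros(3)]))
        assert np.allclose(A.twolink_fk_velocity(arm, x[:3], x[3:]), v, atol=1e-9)

    def test_dimension_mismatch(self, rng):
        jb = K.constrained_jacobian(random_twolink(rng))
        with pytest.raises(UsageError):
            K.solve_joint_rates(jb, np.zeros(3))


class TestIntegration:
    def test_zero_omega_fixed_point(self, rng):
        r = make_rotation(RotationSpec(random_axis(rng), 0.7))
        for method in K.INTEGRATORS:
            assert np.allclose(K.integrate_step(r, np.zeros(3), 1e-3, method), r)

    def test_exp_map_exact_for_constant_axis(self):
        r = make_rotation(RotationSpec(np.array([0.0, 0, 1]), 0.0))
        omega = np.array([0.0, 0, 2.0])
        for _ in range(100):
            r = K.integrate_step(r, omega, 1e-2, "exp_map")
        expected = make_rotation(RotationSpec(np.array([0.0, 0, 1]), 2.0))
        assert np.allclose(r, expected, atol=1e-12)

    def test_euler_renorm_output_unit_and_close_to_exp(self, rng):
        r = make_rotation(RotationSpec(random_axis(rng), 0.5))
        omega = rng.normal(size=3)
        divergences = []
        for dt in (1e-2, 1e-3):
            a = K.integrate_step(r, omega, dt, "euler_renorm")
            b = K.integrate_step(r, omega, dt, "exp_map")
            assert np.linalg.norm(a[:4]) == pytest.approx(1.0)
            divergences.append(np.max(np.abs(a - b)))
        # per-step disagreement shrinks like O(dt²)
        assert divergences[0] / divergences[1] > 30


class TestStability:
    def test_max_stable_gain_values(self):
        assert K.max_stable_gain(1e-3) == pytest.approx(2000.0)
        assert K.max_stable_gain(2e-3) == pytest.approx(1000.0)

    def test_recursion_bounded_vs_divergent(self):
        k_max = K.max_stable_gain(1e-3)
        below = K.error_recursion(k_max * 0.99, 1e-3, e0=1.0, n_steps=500)
        above = K.error_recursion(k_max * 1.01, 1e-3, e0=1.0, n_steps=500)
        assert np.max(np.abs(below)) <= 1.0 + 1e-12
        assert np.abs(above[-1]) > 10.0


class TestCLIK:
    def test_stationary_target_zero_rates(self):
        arm = twolink_pose_for_point([20.0, 30, 10])
        p0 = E.decode_point(A.twolink_fk_position(arm))
        n = 20
        traj = Trajectory(t=np.arange(n) * 1e-3, pos=np.tile(p0[:, None], n), vel=np.zeros((3, n)))
        res = K.clik_track(arm, traj, K.CLIKConfig(k1=1000.0, dt=1e-3))
        assert res.max_error < 1e-12
        assert np.max(np.abs(res.omega)) < 1e-9

    def test_error_decays_geometrically_without_feedforward(self):
        # start offset from the target, no feedforward velocity: per-step
        # error contraction ratio approaches |1 − k1·dt|
        arm = twolink_pose_for_point([20.0, 30, 10])
        target = E.decode_point(A.twolink_fk_position(arm)) + np.array([0.5, 0, 0])
        n = 12
        k1, dt = 400.0, 1e-3
        traj = Trajectory(t=np.arange(n) * dt, pos=np.tile(target[:, None], n), vel=np.zeros((3, n)))
        res = K.clik_track(arm, traj, K.CLIKConfig(k1=k1, dt=dt))
        ratios = res.errors[1:6] / res.errors[:5]
        assert np.allclose(ratios, 1.0 - k1 * dt, atol=0.02)

    def test_tracks_reach_protocol_scaled_down(self):
        res, traj = simulate_reach(duration=0.2, peak_speed=60.0, dt=1e-3, k1=1000.0)
        assert res.max_error < 0.02
        # FK of the recovered joints reproduces the commanded path
        for i in (0, len(res.t) // 2, len(res.t) - 1):
            arm = A.TwoLinkArm(30, 30, res.r_ub[:, i], res.r_lu[:, i])
            assert np.linalg.norm(E.decode_point(A.twolink_fk_position(arm)) - traj.pos[:, i]) < 0.02

    def test_unstable_gain_diverges(self):
        arm, traj = straight_reach(duration=0.15, peak_speed=60.0, dt=1e-3)
        with pytest.warns(UserWarning, match="stability"):
            with pytest.raises(DivergenceError):
                K.clik_track(arm, traj, K.CLIKConfig(k1=2500.0, dt=1e-3))


class TestThreeLinkIK:
    def test_task_jacobian_zero_rates(self, rng):
        arm = A.ThreeLinkArm(
            30, 30, 15,
            make_rotation(RotationSpec(random_axis(rng), 0.5)),
            make_rotation(RotationSpec(A.N_ELBOW, 1.2)),
            make_rotation(RotationSpec(random_axis(rng), -0.4)),
        )
        jb = K.threelink_task_jacobian(arm)
        assert np.allclose(jb.j @ np.zeros(9), 0.0)

    def test_task_jacobian_matches_rates(self, rng):
        from dqkin.quat import qvec

        for _ in range(20):
            arm = A.ThreeLinkArm(
                30, 30, 15,
                make_rotation(RotationSpec(random_axis(rng), rng.uniform(-1.5, 1.5))),
                make_rotation(RotationSpec(A.N_ELBOW, rng.uniform(0.3, 2.2))),
                make_rotation(RotationSpec(random_axis(rng), rng.uniform(-1.5, 1.5))),
            )
            om = rng.normal(size=9)
            jb = K.threelink_task_jacobian(arm)
            v = A.threelink_point_rate(arm, om[:3], om[3:6], om[6:])
            ndot = qvec(A.threelink_line_rate(arm, om[:3], om[3:6], om[6:])[:4])
            assert np.allclose(jb.j[:6] @ om, np.concatenate([v, ndot]), atol=1e-9)

    def test_clik_recovers_fk_path(self, rng):
        """Parameter recovery: track the FK path of a known smooth joint motion."""
        from dqkin.quat import qvec

        axs, axw = random_axis(rng), random_axis(rng)
        dt, T = 2e-3, 0.3
        n = int(T / dt) + 1
        t = np.arange(n) * dt
        tau = t / T
        s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
        sd = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / T
        spans = np.array([0.7, -0.6, 0.7])

        def arm_at(i):
            return A.ThreeLinkArm(
                30, 30, 15,
                make_rotation(RotationSpec(axs, 0.2 + spans[0] * s[i])),
                make_rotation(RotationSpec(A.N_ELBOW, 1.2 + spans[1] * s[i])),
                make_rotation(RotationSpec(axw, 0.1 + spans[2] * s[i])),
            )

        pos, vel, dirs, dirr = (np.zeros((3, n)) for _ in range(4))
        for i in range(n):
            a3 = arm_at(i)
            om = (spans[0] * sd[i] * axs, spans[1] * sd[i] * A.N_ELBOW, spans[2] * sd[i] * axw)
            pos[:, i] = E.decode_point(A.threelink_point_fk(a3))
            dirs[:, i] = E.line_direction(A.threelink_line_fk(a3))
            vel[:, i] = A.threelink_point_rate(a3, *om)
            dirr[:, i] = qvec(A.threelink_line_rate(a3, *om)[:4])

        res = K.threelink_clik_track(arm_at(0), t, pos, vel, dirs, dirr, K.CLIKConfig(k1=500.0, dt=dt))
        assert res.max_error < 0.1
        assert np.degrees(np.max(res.direction_errors)) < 0.1
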