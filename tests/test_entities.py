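"""Point/line encodings and sandwich transforms: geometric oracles and invariants."""

import numpy as np
import pytest

from dqkin import entities as E
from dqkin import quat as Q
from dqkin import rigid as R
from dqkin.errors import DQKinError, NonUnitError, UsageError
from dqkin.fixtures import finite_diff, random_unit_dq, to_homogeneous

from conftest import random_axis, random_rotation_spec


class TestEncodings:
    def test_origin_point_is_identity(self):
        assert np.allclose(E.encode_point([0, 0, 0]), Q.dq_identity())

    def test_point_round_trip(self, rng):
        x = rng.normal(size=3) * 10
        assert np.allclose(E.decode_point(E.encode_point(x)), x)

    def test_line_moment_by_hand(self):
        line = E.encode_line([0, 0, 1], [1, 0, 0])
        assert np.allclose(E.line_direction(line), [0, 0, 1])
        assert np.allclose(E.line_moment(line), [0, -1, 0])

    def test_line_independent_of_point_choice(self, rng):
        n = random_axis(rng)
        p = rng.normal(size=3) * 5
        assert np.allclose(E.encode_line(n, p), E.encode_line(n, p + 2.5 * n), atol=1e-12)

    def test_lines_are_unit(self, rng):
        line = E.encode_line(random_axis(rng), rng.normal(size=3) * 5)
        assert Q.is_unit(line, tol=1e-9)

    def test_decode_line_closest_point(self, rng):
        n, p = np.array([0.0, 0, 1]), np.array([1.0, 0, 0])
        nn, pc = E.decode_line(E.encode_line(n, p))
        assert np.allclose(nn, n)
        assert np.allclose(pc, [1, 0, 0])
        assert abs(np.dot(nn, pc)) < 1e-12
        # origin line has zero moment and closest point at the origin
        _, pc0 = E.decode_line(E.encode_line(n, np.zeros(3)))
        assert np.allclose(pc0, 0.0)

    def test_encode_decode_round_trip(self, rng):
        for _ in range(20):
            n = random_axis(rng)
            p = rng.normal(size=3) * 8
            line = E.encode_line(n, p)
            nn, pc = E.decode_line(line)
            assert np.allclose(E.encode_line(nn, pc), line, atol=1e-12)

    def test_invalid_line_rejected(self):
        bad = Q.dq(Q.pure([0, 0, 1.0]), Q.pure([0, 0, 1.0]))  # moment ∥ direction
        with pytest.raises(DQKinError, match="Plücker|unit-direction"):
            E.decode_line(bad)


class TestPointTransforms:
    def test_identity_leaves_point(self, rng):
        x = E.encode_point(rng.normal(size=3))
        assert np.allclose(E.transform_point(Q.dq_identity(), x, "active"), x)

    def test_active_rotation_quarter_turn(self):
        d = R.make_rotation(axis=[0, 0, 1], angle=np.pi / 2)
        out = E.decode_point(E.transform_point(d, E.encode_point([1, 0, 0]), "active"))
        assert np.allclose(out, [0, 1, 0], atol=1e-12)

    def test_passive_translation(self):
        d = R.make_translation(axis=[0, 0, 1], distance=5.0)
        out = E.decode_point(E.transform_point(d, E.encode_point([1, 2, 3]), "passive"))
        assert np.allclose(out, [1, 2, 8])

    def test_rotation_modes_mutually_inverse(self, rng):
        d = R.make_rotation(random_rotation_spec(rng))
        x = E.encode_point(rng.normal(size=3) * 5)
        back = E.transform_point(d, E.transform_point(d, x, "active"), "passive")
        assert np.allclose(back, x, atol=1e-12)

    def test_translation_modes_coincide(self, rng):
        # T̄* = T: both modes displace by +d·t — the documented divergence
        # from the rotation case
        d = R.make_translation(axis=random_axis(rng), distance=4.0)
        x = E.encode_point(rng.normal(size=3))
        assert np.allclose(
            E.transform_point(d, x, "active"), E.transform_point(d, x, "passive"), atol=1e-12
        )

    def test_matches_homogeneous_action(self, rng):
        batch = random_unit_dq(30, seed=21)
        for i in range(30):
            d = batch[:, i]
            x = rng.normal(size=3) * 10
            out = E.decode_point(E.transform_point(d, E.encode_point(x), "active"))
            assert np.allclose(out, (to_homogeneous(d) @ np.r_[x, 1.0])[:3], atol=1e-9)

    def test_non_unit_operator_rejected(self, rng):
        with pytest.raises(NonUnitError, match="residuals"):
            E.transform_point(rng.normal(size=8) * 3, E.encode_point([1, 2, 3]))

    def test_unknown_mode(self):
        with pytest.raises(UsageError, match="mode"):
            E.transform_point(Q.dq_identity(), E.encode_point([0, 0, 0]), "sideways")

    def test_distance_preservation(self, rng):
        cloud = rng.normal(size=(3, 12)) * 10
        d = random_unit_dq(1, seed=5)[:, 0]
        moved = E.transform_point(d, E.encode_point(cloud), "active")[5:]
        for mode_cloud in (moved,):
            before = np.linalg.norm(cloud[:, :, None] - cloud[:, None, :], axis=0)
            after = np.linalg.norm(mode_cloud[:, :, None] - mode_cloud[:, None, :], axis=0)
            assert np.allclose(before, after, atol=1e-9)


class TestLineTransforms:
    def test_rotate_line_through_origin(self):
        d = R.make_rotation(axis=[0, 0, 1], angle=np.pi / 2)
        line = E.encode_line([1, 0, 0], [0, 0, 0])
        out = E.transform_line(d, line, "active")
        n, pc = E.decode_line(out)
        assert np.allclose(n, [0, 1, 0], atol=1e-12)
        assert np.allclose(pc, 0.0, atol=1e-12)

    def test_translation_matches_reencoding(self, rng):
        n = random_axis(rng)
        p = rng.normal(size=3) * 5
        t_axis = random_axis(rng)
        d = R.make_translation(axis=t_axis, distance=3.5)
        out = E.transform_line(d, E.encode_line(n, p), "active")
        assert np.allclose(out, E.encode_line(n, p + 3.5 * t_axis), atol=1e-12)

    def test_incidence_preserved(self, rng):
        for i in range(10):
            n = random_axis(rng)
            p = rng.normal(size=3) * 6
            d = random_unit_dq(1, seed=100 + i)[:, 0]
            point_on_line = p + rng.normal() * n
            line_t = E.transform_line(d, E.encode_line(n, p), "active")
            pt_t = E.decode_point(E.transform_point(d, E.encode_point(point_on_line), "active"))
            nn, pc = E.decode_line(line_t)
            assert np.linalg.norm(np.cross(pt_t - pc, nn)) < 1e-9
            # Plücker constraint survives the transform
            assert abs(np.dot(nn, E.line_moment(line_t))) < 1e-9


class TestRates:
    def test_static_everything_gives_zero(self, rng):
        d = random_unit_dq(1, seed=2)[:, 0]
        x = E.encode_point(rng.normal(size=3))
        out = E.transformed_point_rate(d, np.zeros(8), x)
        assert np.allclose(out, 0.0)
        line = E.encode_line(random_axis(rng), rng.normal(size=3))
        assert np.allclose(E.transformed_line_rate(d, np.zeros(8), line), 0.0)

    def test_static_rotating_frame_rotates_velocity(self, rng):
        # Ω = 0 and pure rotation: V' is V with rotated coordinates
        spec = random_rotation_spec(rng)
        d = R.make_rotation(spec)
        x = rng.normal(size=3)
        v = rng.normal(size=3)
        out = E.transformed_point_rate(d, np.zeros(8), E.encode_point(x), E.point_velocity_dq(v), "passive")
        expected = E.transform_point(d, E.encode_point(v), "passive")[5:]
        assert np.allclose(out[5:], expected, atol=1e-12)

    def test_translating_frame_rate(self):
        # moving frame along t with ḋ: V″ = ε(ẋ + ḋ t)
        t_axis = np.array([0.0, 1.0, 0.0])
        d = R.make_translation(axis=t_axis, distance=1.0)
        ddot = R.translation_rate(R.TranslationSpec(t_axis, 1.0), d_dot=2.0)
        out = E.transformed_point_rate(d, ddot, E.encode_point([5.0, 1, 2]), E.point_velocity_dq([1.0, 0, 0]), "passive")
        assert np.allclose(out[5:], [1.0, 2.0, 0.0], atol=1e-12)

    def test_screw_motion_point_rate_finite_difference(self, rng):
        n = random_axis(rng)
        a = rng.normal(size=3) * 4
        x0 = rng.normal(size=3) * 6

        def pose(t):
            return R.make_screw(R.ScrewSpec(n, 0.4 + 0.9 * t, a, 1.0 + 1.5 * t))

        def moved(t):
            return E.transform_point(pose(t), E.encode_point(x0), "active")

        t0 = 0.25
        mdot = R.screw_rate(
            R.ScrewSpec(n, 0.4 + 0.9 * t0, a, 1.0 + 1.5 * t0), theta_dot=0.9, d_dot=1.5
        )
        out = E.transformed_point_rate(pose(t0), mdot, E.encode_point(x0), mode="active")
        assert np.allclose(out, finite_diff(moved, t0, 1e-6), atol=1e-7)

    def test_rotating_line_rate_analytic(self):
        omega = np.array([0.0, 0.0, 1.3])
        line = E.encode_line([1.0, 0, 0], [0.0, 0, 0])
        d = Q.dq_identity()
        ddot = R.rotation_rate(Q.dq_identity(), omega)
        out = E.transformed_line_rate(d, ddot, line, mode="active")
        # active sandwich R* L R: direction rotates with +Ω at the identity
        assert np.allclose(out[1:4], np.cross(omega, [1, 0, 0]), atol=1e-12)
        assert np.allclose(np.linalg.norm(out[1:4]), np.linalg.norm(omega))

    def test_line_rate_finite_difference(self, rng):
        n = random_axis(rng)
        p = rng.normal(size=3) * 5
        a = rng.normal(size=3) * 3
        axis = random_axis(rng)
        line = E.encode_line(n, p)

        def pose(t):
            return R.make_screw(R.ScrewSpec(axis, 0.2 + 1.1 * t, a, 0.5 * t))

        def moved(t):
            return E.transform_line(pose(t), line, "active")

        t0 = 0.3
        mdot = R.screw_rate(R.ScrewSpec(axis, 0.2 + 1.1 * t0, a, 0.5 * t0), theta_dot=1.1, d_dot=0.5)
        out = E.transformed_line_rate(pose(t0), mdot, line, mode="active")
        assert np.allclose(out, finite_diff(moved, t0, 1e-6), atol=1e-7)
        # direction rate stays perpendicular to the direction
        n_t = E.line_direction(moved(t0))
        assert abs(np.dot(out[1:4], n_t)) < 1e-9

    def test_line_rate_independent_of_point_parameterization(self, rng):
        n = random_axis(rng)
        ndot = np.cross(rng.normal(size=3), n)  # keep ṅ ⟂ n
        p, pdot = rng.normal(size=3), rng.normal(size=3)
        lam, mu = 1.7, -0.4
        a = E.line_rate_from_point(n, ndot, p, pdot)
        b = E.line_rate_from_point(n, ndot, p + lam * n, pdot + mu * n + lam * ndot)
        assert np.allclose(a, b, atol=1e-12)
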