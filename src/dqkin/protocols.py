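"""Packaged end-to-end simulation protocols.

The flagship protocol is a straight-line point-to-point reach of the
four-dof two-link arm with a bell-shaped (minimum-jerk) speed profile —
the standard kinematic signature of human reaching — tracked by the
closed-loop pseudo-inverse IK solver.  Defaults: 800 ms movement, 100
cm/s peak speed, 1 ms timestep, feedback gain k₁ = 1000 1/s, link
lengths a = b = 30 cm, reach direction (1,1,1)/√3 ("to the right, up
and away" from the shoulder).

The start pose is built so the elbow stays flexed near 90° along the
whole path: the start point sits at radius ``start_radius`` (default 45
cm) and the path is placed symmetrically about its closest point to the
shoulder, keeping the hand well inside the workspace and away from the
aligned-arm singularity.
"""

from __future__ import annotations

import numpy as np

from .arm import N_ELBOW, TwoLinkArm
from .entities import decode_point
from .errors import UsageError
from .fixtures import Trajectory, TrajectorySpec, bell_trajectory
from .ik import CLIKConfig, IKResult, clik_track
from .arm import twolink_fk_position
from .rigid import RotationSpec, make_rotation

__all__ = ["twolink_pose_for_point", "straight_reach", "simulate_reach"]


def twolink_pose_for_point(point, a: float = 30.0, b: float = 30.0) -> TwoLinkArm:
    """A two-link arm pose whose end-effector sits at ``point`` (elbow about z).

    The elbow angle follows from the law of cosines,
    ``cos θ = (‖p‖² − a² − b²)/(2ab)``; the shoulder rotation is the
    minimal rotation taking the in-plane hand position onto ``point``.
    One of the infinitely many poses (self-rotation about the
    shoulder–hand axis is free); deterministic by construction.
    """
    p = np.asarray(point, dtype=float)
    r = float(np.linalg.norm(p))
    if not abs(a - b) <= r <= a + b:
        raise UsageError(f"point at radius {r:.3g} cm is outside the [{abs(a-b)}, {a+b}] cm workspace annulus")
    cos_theta = np.clip((r**2 - a**2 - b**2) / (2 * a * b), -1.0, 1.0)
    theta = float(np.arccos(cos_theta))
    r_lu = make_rotation(RotationSpec(N_ELBOW, theta))
    # hand position before the shoulder rotation, in the elbow plane
    q = np.array([a + b * np.cos(theta), b * np.sin(theta), 0.0])
    axis = np.cross(q, p)
    if np.linalg.norm(axis) < 1e-12:
        r_ub = make_rotation(RotationSpec(N_ELBOW, 0.0))
    else:
        angle = float(np.arccos(np.clip(np.dot(q, p) / (np.linalg.norm(q) * r), -1.0, 1.0)))
        r_ub = make_rotation(RotationSpec(axis / np.linalg.norm(axis), angle))
    arm = TwoLinkArm(a, b, r_ub, r_lu)
    resid = np.linalg.norm(decode_point(twolink_fk_position(arm)) - p)
    if resid > 1e-6:
        raise UsageError(f"pose construction failed (residual {resid:.3g} cm)")
    return arm


def straight_reach(
    duration: float = 0.8,
    peak_speed: float = 100.0,
    dt: float = 1e-3,
    direction=(1.0, 1.0, 1.0),
    a: float = 30.0,
    b: float = 30.0,
    start_radius: float = 45.0,
) -> tuple[TwoLinkArm, Trajectory]:
    """Build the start pose and the minimum-jerk straight-line trajectory.

    The start point is chosen so the chord of length D (the reach
    displacement) lies symmetrically about its perpendicular foot from
    the shoulder, with endpoints at ``start_radius``.
    """
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    displacement = peak_speed * duration / 1.875
    half = displacement / 2.0
    if start_radius <= half:
        raise UsageError("start_radius must exceed half the reach displacement")
    if start_radius > a + b:
        raise UsageError("start_radius outside the workspace")
    # perpendicular offset from the shoulder to the path line
    w_norm = np.sqrt(start_radius**2 - half**2)
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    w = np.cross(u, helper)
    w = w / np.linalg.norm(w) * w_norm
    start = w - half * u
    spec = TrajectorySpec(duration=duration, direction=u, start=start, dt=dt, peak_speed=peak_speed)
    return twolink_pose_for_point(start, a, b), bell_trajectory(spec)


def simulate_reach(
    duration: float = 0.8,
    peak_speed: float = 100.0,
    dt: float = 1e-3,
    k1: float = 1000.0,
    direction=(1.0, 1.0, 1.0),
    a: float = 30.0,
    b: float = 30.0,
    integrator: str = "euler_renorm",
) -> tuple[IKResult, Trajectory]:
    """Run the full bell-profile reach through the closed-loop IK solver.

    Returns the IK result (joint series and per-step position errors, cm)
    together with the commanded trajectory.
    """
    arm, traj = straight_reach(duration, peak_speed, dt, direction, a, b)
    cfg = CLIKConfig(k1=k1, dt=dt, integrator=integrator)
    return clik_track(arm, traj, cfg), traj
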