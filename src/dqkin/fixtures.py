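"""Synthetic inputs and independent oracles.

This module is first-class library code: it generates the seeded random
rotations / rigid motions and the bell-shaped reaching trajectories used
throughout the package, and provides the independent reference paths the
test-suite checks the algebra against — 4×4 homogeneous-matrix conversion
(built on :mod:`scipy.spatial.transform`, not on this package's own
products) and central finite differences.

The trajectory generator emulates point-to-point reaches with the
bell-shaped speed profile reported for human hand movements; the single
supported profile is minimum-jerk, ``s(τ) = D(10τ³ − 15τ⁴ + 6τ⁵)``,
whose peak speed is ``1.875·D/T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DQKinError, UsageError

__all__ = [
    "TrajectorySpec",
    "Trajectory",
    "bell_trajectory",
    "random_rotation",
    "random_unit_dq",
    "to_homogeneous",
    "from_homogeneous",
    "finite_diff",
]


# ---------------------------------------------------------------------------
# bell-shaped (minimum-jerk) trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectorySpec:
    """Straight-line reach with a minimum-jerk speed profile.

    Exactly one of ``peak_speed`` (cm/s) or ``displacement`` (cm) is given;
    the other follows from ``peak = 1.875·D/T``.  ``direction`` must be a
    unit 3-vector; ``duration`` and ``dt`` are seconds, ``start`` is cm.
    """

    duration: float
    direction: np.ndarray
    start: np.ndarray = field(default_factory=lambda: np.zeros(3))
    dt: float = 1e-3
    peak_speed: float | None = None
    displacement: float | None = None
    profile: str = "min_jerk"

    def __post_init__(self):
        if self.duration <= 0 or self.dt <= 0:
            raise UsageError("duration and dt must be positive")
        if self.profile != "min_jerk":
            raise UsageError(f"unsupported profile {self.profile!r}")
        if (self.peak_speed is None) == (self.displacement is None):
            raise UsageError("give exactly one of peak_speed or displacement")
        u = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(u) - 1.0) > 1e-6:
            raise UsageError("direction must be a unit vector")
        object.__setattr__(self, "direction", u / np.linalg.norm(u))
        object.__setattr__(self, "start", np.asarray(self.start, dtype=float))
        if self.displacement is None:
            object.__setattr__(self, "displacement", self.peak_speed * self.duration / 1.875)
        else:
            object.__setattr__(self, "peak_speed", 1.875 * self.displacement / self.duration)


@dataclass(frozen=True)
class Trajectory:
    """Sampled end-effector path: times (N,), positions and velocities (3, N), cm and cm/s."""

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray


def bell_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Sample the minimum-jerk straight-line reach; velocities are analytic derivatives."""
    n_steps = int(round(spec.duration / spec.dt))
    t = np.arange(n_steps + 1) * spec.dt
    tau = t / spec.duration
    s = spec.displacement * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    sdot = spec.displacement / spec.duration * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    pos = spec.start[:, None] + spec.direction[:, None] * s[None, :]
    vel = spec.direction[:, None] * sdot[None, :]
    return Trajectory(t=t, pos=pos, vel=vel)


# ---------------------------------------------------------------------------
# seeded random elements
# ---------------------------------------------------------------------------


def random_rotation(count: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Batch of rotation quaternions (4×N): axis uniform on the sphere, angle ~ U(0, π)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    axis = rng.normal(size=(3, count))
    axis /= np.linalg.norm(axis, axis=0)
    angle = rng.uniform(0.0, np.pi, size=count)
    return np.concatenate([np.cos(angle / 2)[None, :], axis * np.sin(angle / 2)[None, :]], axis=0)


def random_unit_dq(count: int, seed: int | np.random.Generator = 0, trans_scale: float = 10.0) -> np.ndarray:
    """Batch of unit dual quaternions (8×N): random rotation composed with a
    translation whose components are normal with s.d. ``trans_scale`` cm."""
    from .quat import dqmul  # local import keeps module load cheap

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rot = random_rotation(count, rng)
    rot_dq = np.concatenate([rot, np.zeros_like(rot)], axis=0)
    v = rng.normal(scale=trans_scale, size=(3, count))
    trans = np.zeros((8, count))
    trans[0] = 1.0
    trans[5:] = v / 2.0
    return dqmul(trans, rot_dq)


# ---------------------------------------------------------------------------
# homogeneous-matrix conversion (independent reference path)
# ---------------------------------------------------------------------------


def _hamilton(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton quaternion product (ij = k); written out so this reference
    path shares no code with the package's own product."""
    a0, av = a[0], a[1:]
    b0, bv = b[0], b[1:]
    return np.concatenate(
        [
            np.asarray(a0 * b0 - np.dot(av, bv))[None],
            a0 * bv + b0 * av + np.cross(av, bv),
        ]
    )


def to_homogeneous(d, tol: float = 1e-6) -> np.ndarray:
    """4×4 homogeneous rigid-transform matrix acting like the *active* point sandwich.

    ``transform_point(d, encode_point(x), "active")`` equals ``H @ [x, 1]``.
    Composition maps contravariantly: ``to_homogeneous(dqmul(d, e)) ==
    to_homogeneous(e) @ to_homogeneous(d)`` (in the active sandwich the
    left factor of the product acts first).
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (8,):
        raise UsageError("to_homogeneous expects a single (8,) dual quaternion")
    n0 = np.linalg.norm(d[:4])
    if abs(n0 - 1.0) > tol:
        raise DQKinError("to_homogeneous requires a unit dual quaternion")
    w, x, y, z = d[:4]
    rot = Rotation.from_quat([x, y, z, w]).as_matrix()
    t = 2.0 * _hamilton(d[4:], np.array([w, -x, -y, -z]))[1:]
    h = np.eye(4)
    h[:3, :3] = rot
    h[:3, 3] = t
    return h


def from_homogeneous(h, tol: float = 1e-6) -> np.ndarray:
    """Unit dual quaternion for a rigid 4×4 matrix (canonical sign: real scalar ≥ 0)."""
    h = np.asarray(h, dtype=float)
    if h.shape != (4, 4):
        raise UsageError("from_homogeneous expects a 4×4 matrix")
    r = h[:3, :3]
    if np.max(np.abs(r.T @ r - np.eye(3))) > tol or np.linalg.det(r) < 0:
        raise DQKinError("matrix is not a rigid transform (orthonormal, det = +1)")
    if np.max(np.abs(h[3] - [0, 0, 0, 1])) > tol:
        raise DQKinError("matrix is not homogeneous (last row must be [0,0,0,1])")
    x, y, z, w = Rotation.from_matrix(r).as_quat()
    real = np.array([w, x, y, z])
    if real[0] < 0:
        real = -real
    t_pure = np.concatenate([[0.0], h[:3, 3]])
    dual = 0.5 * _hamilton(t_pure, real)
    return np.concatenate([real, dual])


# ---------------------------------------------------------------------------
# finite differences
# ---------------------------------------------------------------------------


def finite_diff(f, t: float, h: float = 1e-6) -> np.ndarray:
    """Central difference ``(f(t+h) − f(t−h)) / 2h`` on any array-valued path.

    Second-order accurate; used as the independent oracle for every
    analytic velocity operator in the package.
    """
    if h <= 0:
        raise UsageError("finite_diff step h must be positive")
    return (np.asarray(f(t + h), dtype=float) - np.asarray(f(t - h), dtype=float)) / (2.0 * h)
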