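"""Rigid-motion operators: rotation, translation, offset rotation and screw motion.

All constructors return unit dual quaternions in the 8-vector encoding of
:mod:`dqkin.quat` and build the *operator* only; whether it is applied as a
passive (frame) or active (mobile entity) transform — and with which
conjugate — is decided at application time in :mod:`dqkin.entities`.

Angles are radians, distances are cm throughout.  Rotation axes must be
unit vectors; an axis whose norm is off by at most ``AXIS_SNAP_TOL`` is
renormalized with a warning, anything worse raises.

Velocity conventions
--------------------
The rotational velocity Ω (a pure quaternion, rad/s) is *not* the time
derivative of the rotation: the derivative is ``Ṙ = ½ R Ω`` in this
algebra's product order, and conversely ``Ω = 2 R* Ṙ``.  A translation
moving with ``v = ḋ t + d ṫ`` has derivative ``Ṫ = ε v/2``.  The screw
rate combines a translational, an axis-offset and a rotational term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import SingularElementError, UsageError
from .quat import (
    dq,
    dq_from_quat,
    dq_identity,
    dqconj,
    dqmul,
    pure,
    qconj,
    qmul,
    quat,
)

AXIS_SNAP_TOL = 1e-6
AXIS_ZERO_TOL = 1e-12

__all__ = [
    "RotationSpec",
    "TranslationSpec",
    "ScrewSpec",
    "unit_axis",
    "make_rotation",
    "make_translation",
    "translation_from_vector",
    "make_offset_rotation",
    "offset_rotation_sandwich",
    "make_screw",
    "screw_compose",
    "rotation_rate",
    "angular_velocity_from",
    "translation_rate",
    "screw_rate",
]


def unit_axis(n, *, what: str = "axis") -> np.ndarray:
    """Validate/normalize a rotation or translation axis to unit length."""
    n = np.asarray(n, dtype=float)
    if n.shape != (3,):
        raise UsageError(f"{what} must be a 3-vector, got shape {n.shape}")
    norm = float(np.linalg.norm(n))
    if norm < AXIS_ZERO_TOL:
        raise SingularElementError(f"{what} has (near-)zero length")
    if abs(norm - 1.0) > AXIS_SNAP_TOL:
        raise UsageError(f"{what} is not unit length (‖·‖ = {norm:.6g})")
    if abs(norm - 1.0) > 1e-12:
        warnings.warn(f"{what} renormalized (‖·‖ − 1 = {norm - 1.0:.2e})", stacklevel=3)
    return n / norm


@dataclass(frozen=True)
class RotationSpec:
    """Axis–angle rotation about an axis through the origin (Euler's theorem)."""

    axis: np.ndarray
    angle: float  # radians

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        angle = float(self.angle)
        if angle == 0.0 and np.linalg.norm(axis) < AXIS_ZERO_TOL:
            axis = np.zeros(3)  # degenerate axis is fine for the identity rotation
        else:
            axis = unit_axis(axis, what="rotation axis")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "angle", angle)


@dataclass(frozen=True)
class TranslationSpec:
    """Translation of signed distance d along a unit axis t."""

    axis: np.ndarray
    distance: float  # cm

    def __post_init__(self):
        object.__setattr__(self, "axis", unit_axis(self.axis, what="translation axis"))
        object.__setattr__(self, "distance", float(self.distance))


@dataclass(frozen=True)
class ScrewSpec:
    """Rotation of ``angle`` about the line through ``point`` with direction
    ``axis``, combined with a slide of ``slide`` along that axis (Chasles)."""

    axis: np.ndarray
    angle: float  # radians
    point: np.ndarray = field(default_factory=lambda: np.zeros(3))  # any point on the axis line
    slide: float = 0.0  # cm along the axis

    def __post_init__(self):
        object.__setattr__(self, "axis", unit_axis(self.axis, what="screw axis"))
        object.__setattr__(self, "angle", float(self.angle))
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "slide", float(self.slide))


def _rot_quat(axis, angle) -> np.ndarray:
    return quat(np.cos(angle / 2.0), np.asarray(axis) * np.sin(angle / 2.0))


def make_rotation(spec: RotationSpec | None = None, *, axis=None, angle=None) -> np.ndarray:
    """Rotation dual quaternion ``cos(θ/2) + n sin(θ/2)`` (zero dual part)."""
    if spec is None:
        spec = RotationSpec(np.asarray(axis, dtype=float), angle)
    if spec.angle == 0.0:
        return dq_identity()
    return dq_from_quat(_rot_quat(spec.axis, spec.angle))


def make_translation(spec: TranslationSpec | None = None, *, axis=None, distance=None) -> np.ndarray:
    """Translation dual quaternion ``1 + ε (d/2) t``."""
    if spec is None:
        spec = TranslationSpec(np.asarray(axis, dtype=float), distance)
    return dq(np.array([1.0, 0, 0, 0]), pure(spec.axis * (spec.distance / 2.0)))


def translation_from_vector(v) -> np.ndarray:
    """Translation dual quaternion ``1 + ε v/2`` for an arbitrary displacement v."""
    v = np.asarray(v, dtype=float)
    return dq(np.array([1.0, 0, 0, 0]), pure(v / 2.0))


def offset_rotation_sandwich(spec: RotationSpec, point) -> np.ndarray:
    """Offset rotation built as the sandwich ``R_T = T_L* R T_L``, ``T_L = 1 + ε a/2``."""
    t_l = translation_from_vector(point)
    r = make_rotation(spec)
    return dqmul(dqconj(t_l, "quaternion"), dqmul(r, t_l))


def make_offset_rotation(spec: RotationSpec | None = None, point=(0.0, 0.0, 0.0), *, axis=None, angle=None) -> np.ndarray:
    """Rotation about an axis line through ``point`` (closed form).

    ``R_T = (cos(θ/2) + n sin(θ/2)) + ε (a⃗ ∧ n⃗) sin(θ/2)``; the moment
    ``a⃗ ∧ n⃗`` makes the result independent of which axis point is given.
    """
    if spec is None:
        spec = RotationSpec(np.asarray(axis, dtype=float), angle)
    a = np.asarray(point, dtype=float)
    s = np.sin(spec.angle / 2.0)
    real = quat(np.cos(spec.angle / 2.0), spec.axis * s)
    dual = pure(np.cross(a, spec.axis) * s)
    return dq(real, dual)


def make_screw(spec: ScrewSpec) -> np.ndarray:
    """Screw-motion dual quaternion (closed form).

    ``M = (cos(θ/2) + n sin(θ/2))
        + ε(−(d/2) sin(θ/2) + n (d/2) cos(θ/2) + (a⃗ ∧ n⃗) sin(θ/2))``
    """
    c, s = np.cos(spec.angle / 2.0), np.sin(spec.angle / 2.0)
    half_d = spec.slide / 2.0
    real = quat(c, spec.axis * s)
    dual = quat(-half_d * s, spec.axis * half_d * c + np.cross(spec.point, spec.axis) * s)
    return dq(real, dual)


def screw_compose(spec: ScrewSpec) -> np.ndarray:
    """Screw motion as the composition ``M = T · R_T`` (slide times offset rotation).

    Agrees with :func:`make_screw`; kept as an independent construction.
    """
    t = make_translation(axis=spec.axis, distance=spec.slide)
    r_t = make_offset_rotation(RotationSpec(spec.axis, spec.angle), spec.point)
    return dqmul(t, r_t)


# ---------------------------------------------------------------------------
# velocities
# ---------------------------------------------------------------------------


def _pure_omega(omega) -> np.ndarray:
    """Coerce a rotational velocity to a pure quaternion, rejecting scalar parts."""
    omega = np.asarray(omega, dtype=float)
    if omega.shape == (3,):
        return pure(omega)
    if omega.shape == (4,):
        if abs(omega[0]) > 1e-12:
            raise UsageError("rotational velocity must be a pure quaternion (zero scalar part)")
        return omega
    raise UsageError(f"rotational velocity must be a 3- or 4-vector, got shape {omega.shape}")


def rotation_rate(r, omega) -> np.ndarray:
    """Derivative ``Ṙ = ½ R Ω`` of a rotation dual quaternion.

    ``r`` may be a quaternion (4-vector) or a rotation dual quaternion
    (8-vector with zero dual part); the result matches the input rank.
    """
    om = _pure_omega(omega)
    r = np.asarray(r, dtype=float)
    if r.shape == (4,):
        return 0.5 * qmul(r, om)
    return 0.5 * dqmul(r, dq_from_quat(om))


def angular_velocity_from(r, rdot) -> np.ndarray:
    """Recover the rotational-velocity vector from R and Ṙ: ``Ω = 2 R* Ṙ``."""
    r = np.asarray(r, dtype=float)
    rdot = np.asarray(rdot, dtype=float)
    r0 = r[:4] if r.shape == (8,) else r
    rd0 = rdot[:4] if rdot.shape == (8,) else rdot
    return qmul(2.0 * qconj(r0), rd0)[1:]


def translation_rate(spec: TranslationSpec, d_dot: float = 0.0, axis_dot=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Derivative ``Ṫ = ε v/2`` with ``v = ḋ t + d ṫ`` (zero real part)."""
    v = d_dot * spec.axis + spec.distance * np.asarray(axis_dot, dtype=float)
    return dq(np.zeros(4), pure(v / 2.0))


def screw_rate(
    spec: ScrewSpec,
    theta_dot: float = 0.0,
    d_dot: float = 0.0,
    point_dot=(0.0, 0.0, 0.0),
    omega=None,
) -> np.ndarray:
    """Derivative of the screw-motion dual quaternion along a parameter path.

    ``Ṁ = Ṫ R_T  +  (Ṫ_L* R + R Ṫ_L)  +  ½ T T_L* R Ω T_L``

    whose terms are the slide velocity along the axis, the translational
    velocity of the axis itself, and the rotational velocity.  ``omega``
    defaults to ``θ̇ n`` (fixed axis direction); pass it explicitly for the
    pure-rotation case with a general instantaneous axis.
    """
    n, a = spec.axis, spec.point
    t = make_translation(axis=n, distance=spec.slide)
    t_l = translation_from_vector(a)
    r = make_rotation(RotationSpec(n, spec.angle))
    r_t = make_offset_rotation(RotationSpec(n, spec.angle), a)

    om = _pure_omega(theta_dot * n if omega is None else omega)
    om_dq = dq_from_quat(om)

    t_dot = dq(np.zeros(4), pure((d_dot / 2.0) * n))
    tl_dot = dq(np.zeros(4), pure(np.asarray(point_dot, dtype=float) / 2.0))

    term_trans = dqmul(t_dot, r_t)
    term_offset = dqmul(dqconj(tl_dot, "quaternion"), r) + dqmul(r, tl_dot)
    term_rot = 0.5 * dqmul(t, dqmul(dqconj(t_l, "quaternion"), dqmul(r, dqmul(om_dq, t_l))))
    return term_trans + term_offset + term_rot
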