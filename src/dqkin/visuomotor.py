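"""Eye–head–shoulder visuomotor reference-frame transformation.

Maps target position and velocity between shoulder-centered shoulder-fixed
(SS) coordinates and eye-centered eye-fixed (EE) coordinates, and projects
onto the retina.  The kinematic chain combines the eye-in-head rotation
R_EH, the eye–head offset translation T_HE, the head-on-shoulder rotation
R_HS and the head–shoulder offset T_SH:

    forward:  P_EE = R_EH T_HE R_HS T_SH · P_SS · T_SH R_HS* T_HE R_EH*
    inverse:  P_SS = T_HS R_HS* T_EH R_EH* · P_EE · R_EH T_EH R_HS T_HS

with T_EH = T_HE* and T_HS = T_SH* (all chain elements are unit dual
quaternions, so inverses are conjugates).  Velocities follow by
differentiating the chains: one commutator term per rotating joint plus
the rotated target velocity.  Frames are tagged on every state and
checked, because silently mixing frames is the classic failure mode of
this computation.

The retinal projection divides by target distance d_P (an eye-centered
quantity); the *inverse* path therefore needs depth d_P — and for
velocity its rate ḋ_P — as explicit inputs.  The library never guesses
depth: missing depth raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .entities import decode_point, decode_velocity, encode_point, point_velocity_dq, transform_point
from .errors import FrameMismatchError, SingularElementError, UsageError
from .quat import dq_from_quat, dqconj, dqmul, pure
from .rigid import RotationSpec, make_rotation, translation_from_vector

__all__ = [
    "BodyGeometry",
    "TargetState",
    "RetinalState",
    "GazeFrames",
    "gaze_forward_position",
    "gaze_forward_velocity",
    "retinal_project",
    "retinal_unproject",
    "gaze_inverse_position",
    "gaze_inverse_velocity",
]

FRAMES = ("SS", "HS", "EH", "EE")


@dataclass(frozen=True)
class BodyGeometry:
    """Eye-head-shoulder kinematic state.

    ``t_he`` is the head position in eye-centered head-fixed coordinates and
    ``t_sh`` the shoulder position in head-centered shoulder-fixed
    coordinates (cm); ``omega_eh`` / ``omega_hs`` are the eye-in-head and
    head-on-shoulder rotational velocities (rad/s).  ``r_eye`` is the
    retinal sphere radius — a pure scale factor, default 1.
    """

    eye_in_head: RotationSpec = field(default_factory=lambda: RotationSpec(np.zeros(3), 0.0))
    head_on_shoulder: RotationSpec = field(default_factory=lambda: RotationSpec(np.zeros(3), 0.0))
    t_he: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t_sh: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega_eh: np.ndarray = field(default_factory=lambda: np.zeros(3))
    omega_hs: np.ndarray = field(default_factory=lambda: np.zeros(3))
    r_eye: float = 1.0

    def __post_init__(self):
        for name in ("t_he", "t_sh", "omega_eh", "omega_hs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise UsageError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)
        if self.r_eye <= 0:
            raise UsageError("r_eye must be positive")


@dataclass(frozen=True)
class TargetState:
    """Target position (cm) and optional velocity (cm/s) tagged with its frame."""

    frame: str
    position: np.ndarray
    velocity: np.ndarray | None = None

    def __post_init__(self):
        if self.frame not in FRAMES:
            raise FrameMismatchError(f"unknown frame {self.frame!r}; expected one of {FRAMES}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.velocity is not None:
            object.__setattr__(self, "velocity", np.asarray(self.velocity, dtype=float))


@dataclass(frozen=True)
class RetinalState:
    """Retinal projection: unit direction on the eye sphere, its rate, and depth.

    ``distance``/``distance_rate`` carry the eye-centered target depth d_P
    (cm) and its rate (cm/s); they are required to invert the projection.
    """

    proj: np.ndarray
    proj_rate: np.ndarray | None = None
    distance: float | None = None
    distance_rate: float | None = None


class GazeFrames(NamedTuple):
    """Target state re-expressed in all frames of the forward chain."""

    ee: TargetState
    eh: TargetState
    hs: TargetState


def _require_frame(s: TargetState, frame: str):
    if s.frame != frame:
        raise FrameMismatchError(f"expected a target state in frame {frame!r}, got {s.frame!r}")


def _chain(g: BodyGeometry):
    r_eh = make_rotation(g.eye_in_head)
    r_hs = make_rotation(g.head_on_shoulder)
    t_he = translation_from_vector(g.t_he)
    t_sh = translation_from_vector(g.t_sh)
    return r_eh, r_hs, t_he, t_sh


def _passive(d, x):
    return decode_point(transform_point(d, encode_point(x), "passive"))


def _sandwich(r, v_dq):
    """R V R* with a rotation dual quaternion (quaternion conjugate)."""
    return dqmul(r, dqmul(v_dq, dqconj(r, "quaternion")))


def _comm(omega, p_dq):
    """½(Ω P − P Ω) for a pure rotational velocity and a point dual quaternion."""
    om = dq_from_quat(pure(np.asarray(omega, dtype=float)))
    return 0.5 * (dqmul(om, p_dq) - dqmul(p_dq, om))


def gaze_forward_position(g: BodyGeometry, s: TargetState) -> GazeFrames:
    """Express an SS-frame target in HS, EH and EE coordinates (passive chain)."""
    _require_frame(s, "SS")
    r_eh, r_hs, t_he, t_sh = _chain(g)
    p_hs = _passive(t_sh, s.position)
    p_eh = _passive(dqmul(t_he, r_hs), p_hs)
    p_ee = _passive(r_eh, p_eh)
    return GazeFrames(
        ee=TargetState("EE", p_ee),
        eh=TargetState("EH", p_eh),
        hs=TargetState("HS", p_hs),
    )


def gaze_forward_velocity(g: BodyGeometry, s: TargetState) -> TargetState:
    """EE-frame target velocity: eye and head commutator terms plus the rotated SS velocity.

    With a static eye-head configuration (both Ω zero) only the last term
    remains — the velocity is merely re-expressed in eye coordinates.
    """
    _require_frame(s, "SS")
    if s.velocity is None:
        raise UsageError("gaze_forward_velocity needs the SS-frame target velocity")
    r_eh, r_hs, t_he, t_sh = _chain(g)
    frames = gaze_forward_position(g, s)
    p_eh_dq = encode_point(frames.eh.position)
    p_hs_dq = encode_point(frames.hs.position)

    term_eye = _sandwich(r_eh, _comm(g.omega_eh, p_eh_dq))
    term_head = _sandwich(r_eh, _sandwich(r_hs, _comm(g.omega_hs, p_hs_dq)))
    term_target = _sandwich(r_eh, _sandwich(r_hs, point_velocity_dq(s.velocity)))
    v_ee = decode_velocity(term_eye + term_head + term_target)
    return TargetState("EE", frames.ee.position, v_ee)


def retinal_project(p_ee, v_ee=None, r_eye: float = 1.0, tol: float = 1e-9) -> RetinalState:
    """Project an EE-frame target onto the eye sphere of radius ``r_eye``.

    ``proj = r_eye·P/d_P`` with ``d_P = ‖P‖``; the projection rate follows
    by the quotient rule with ``ḋ_P = (P·Ṗ)/d_P``.  For isodistance motion
    (ḋ_P = 0) the rate reduces to ``Ṗ/d_P``.
    """
    p = np.asarray(p_ee, dtype=float)
    d = float(np.linalg.norm(p))
    if d <= tol:
        raise SingularElementError("retinal_project: target at the eye center has no projection")
    proj = r_eye * p / d
    if v_ee is None:
        return RetinalState(proj=proj, distance=d)
    v = np.asarray(v_ee, dtype=float)
    d_dot = float(np.dot(p, v)) / d
    proj_rate = r_eye * (v * d - d_dot * p) / d**2
    return RetinalState(proj=proj, proj_rate=proj_rate, distance=d, distance_rate=d_dot)


def retinal_unproject(r: RetinalState, r_eye: float = 1.0) -> tuple[np.ndarray, np.ndarray | None]:
    """Reconstruct EE-frame position (and velocity, if rates are present) from the retina.

    Depth is required: ``P = d_P·proj/r_eye`` and
    ``Ṗ = d_P·projṖ/r_eye + ḋ_P·proj/r_eye``.
    """
    if r.distance is None:
        raise UsageError("depth d_P is required to unproject a retinal state (it is not estimated)")
    p = r.distance * np.asarray(r.proj, dtype=float) / r_eye
    if r.proj_rate is None:
        return p, None
    if r.distance_rate is None:
        raise UsageError("depth rate ḋ_P is required to unproject a retinal velocity")
    v = (r.distance * np.asarray(r.proj_rate, dtype=float) + r.distance_rate * np.asarray(r.proj, dtype=float)) / r_eye
    return p, v


def _inverse_intermediates(g: BodyGeometry, p_ee):
    r_eh, r_hs, t_he, t_sh = _chain(g)
    t_eh = translation_from_vector(-g.t_he)
    p_eh = _passive(dqconj(r_eh, "quaternion"), p_ee)
    p_hs = _passive(dqmul(dqconj(r_hs, "quaternion"), t_eh), p_eh)
    p_ss = _passive(translation_from_vector(-g.t_sh), p_hs)
    return p_ss, p_hs, p_eh


def gaze_inverse_position(g: BodyGeometry, r: RetinalState) -> TargetState:
    """SS-frame target position from a retinal state with known depth."""
    p_ee, _ = retinal_unproject(r, g.r_eye)
    p_ss, _, _ = _inverse_intermediates(g, p_ee)
    return TargetState("SS", p_ss)


def gaze_inverse_velocity(g: BodyGeometry, r: RetinalState) -> TargetState:
    """SS-frame target velocity from a retinal state with known depth and depth rate.

    Exact algebraic inverse of :func:`gaze_forward_velocity`: the eye and
    head commutator terms are removed with opposite sign while the EE
    velocity is rotated back through the chain.
    """
    p_ee, v_ee = retinal_unproject(r, g.r_eye)
    if v_ee is None:
        raise UsageError("gaze_inverse_velocity needs proj_rate and distance_rate")
    r_eh, r_hs, t_he, t_sh = _chain(g)
    p_ss, p_hs, p_eh = _inverse_intermediates(g, p_ee)
    r_hs_c = dqconj(r_hs, "quaternion")
    r_eh_c = dqconj(r_eh, "quaternion")

    term_head = -_comm(g.omega_hs, encode_point(p_hs))
    term_eye = -_sandwich(r_hs_c, _comm(g.omega_eh, encode_point(p_eh)))
    term_target = _sandwich(r_hs_c, _sandwich(r_eh_c, point_velocity_dq(v_ee)))
    v_ss = decode_velocity(term_head + term_eye + term_target)
    return TargetState("SS", p_ss, v_ss)
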