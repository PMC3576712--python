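"""Forward kinematics of two-link and three-link arm models.

Two-link arm (shoulder + elbow, links a and b, cm): the end-effector
position in body-fixed shoulder-centered (BS) coordinates is the nested
active sandwich

    P_BS = R_UB* T_ES R_LU* P_LE R_LU T_ES R_UB

where R_UB is the shoulder rotation (3 dof, axis–angle), R_LU the elbow
rotation (1 dof about n_elbow = [0,0,1] in upper-arm coordinates),
T_ES = 1 + ε[a,0,0]/2 the elbow–shoulder offset and P_LE = 1 + ε[b,0,0]
the hand in lower-arm elbow-centered coordinates.  At the reference
posture (all angles zero) the arm lies extended along +x.

Its velocity, with Ω_UB / Ω_LU the shoulder and elbow rotational
velocities (Ω_LU expressed in upper-arm coordinates), is

    Ṗ_BS = ½(P_BS Ω_UB − Ω_UB P_BS) + R_UB* ½(P_UE Ω_LU − Ω_LU P_UE) R_UB

with P_UE the hand position in upper-arm-fixed *elbow-centered*
coordinates, P_UE = R_LU* P_LE R_LU — the lever arm about the elbow axis.

Three-link arm (shoulder + elbow + wrist, links a, b, c): joints are
modeled as screw operators S_UB = R_UB, S_LU = T_ES* R_LU T_ES,
S_HL = T_WS* R_HL T_WS (rotations about axes offset to the elbow at
[a,0,0] and the wrist at [a+b,0,0]).  The end-effector carries both a
point P₀ = 1 + ε[a+b+c,0,0] and an orientation line L₀ through that
point with direction [0,1,0]; both transform through the same total
screw S_tot = S_HL S_LU S_UB, the point with the mixed conjugate and the
line with the quaternion conjugate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entities import (
    decode_point,
    decode_velocity,
    encode_line,
    encode_point,
    transform_line,
    transform_point,
)
from .errors import UsageError
from .quat import dq_from_quat, dqconj, dqmul, pure
from .rigid import RotationSpec, make_rotation, translation_from_vector

__all__ = [
    "TwoLinkArm",
    "ThreeLinkArm",
    "N_ELBOW",
    "twolink_fk_position",
    "twolink_elbow_position",
    "twolink_hand_in_upper",
    "twolink_fk_velocity",
    "threelink_screws",
    "threelink_line_fk",
    "threelink_point_fk",
    "threelink_line_rate",
    "threelink_point_rate",
]

#: elbow rotation axis in upper-arm-fixed coordinates
N_ELBOW = np.array([0.0, 0.0, 1.0])


def _as_rot_dq(r) -> np.ndarray:
    """Accept a RotationSpec or an (8,) rotation dual quaternion."""
    if isinstance(r, RotationSpec):
        return make_rotation(r)
    r = np.asarray(r, dtype=float)
    if r.shape == (4,):
        return dq_from_quat(r)
    if r.shape != (8,):
        raise UsageError("joint rotation must be a RotationSpec, quaternion or dual quaternion")
    return r


@dataclass
class TwoLinkArm:
    """Two-link arm state: link lengths (cm) and the two joint rotations."""

    a: float = 30.0
    b: float = 30.0
    r_ub: np.ndarray = field(default_factory=lambda: make_rotation(RotationSpec(N_ELBOW, 0.0)))
    r_lu: np.ndarray = field(default_factory=lambda: make_rotation(RotationSpec(N_ELBOW, 0.0)))

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise UsageError("link lengths must be positive")
        self.r_ub = _as_rot_dq(self.r_ub)
        self.r_lu = _as_rot_dq(self.r_lu)

    @classmethod
    def from_angles(cls, phi: float, theta: float, phi_axis=N_ELBOW, a: float = 30.0, b: float = 30.0) -> "TwoLinkArm":
        """Planar-style constructor: shoulder angle φ about ``phi_axis``, elbow angle θ about n_elbow."""
        return cls(
            a=a,
            b=b,
            r_ub=make_rotation(RotationSpec(np.asarray(phi_axis, float), phi)),
            r_lu=make_rotation(RotationSpec(N_ELBOW, theta)),
        )

    @property
    def t_es(self) -> np.ndarray:
        return translation_from_vector([self.a, 0.0, 0.0])

    @property
    def p_le(self) -> np.ndarray:
        return encode_point([self.b, 0.0, 0.0])


def twolink_hand_in_upper(arm: TwoLinkArm) -> np.ndarray:
    """P_UE: hand position in upper-arm-fixed elbow-centered coordinates (point DQ).

    This is the elbow-relative lever arm R_LU* P_LE R_LU — the chain of
    the full FK truncated before both the elbow–shoulder offset and the
    shoulder sandwich, since the elbow-centered frame shares the elbow
    origin and the upper-arm orientation.
    """
    return transform_point(arm.r_lu, arm.p_le, "active")


def twolink_elbow_position(arm: TwoLinkArm) -> np.ndarray:
    """Elbow position in BS coordinates (3-vector): the T_ES-only sub-chain."""
    elbow = transform_point(arm.t_es, encode_point([0.0, 0.0, 0.0]), "active")
    return decode_point(transform_point(arm.r_ub, elbow, "active"))


def twolink_fk_position(arm: TwoLinkArm) -> np.ndarray:
    """End-effector point DQ in BS coordinates (nested active sandwiches)."""
    inner = transform_point(arm.r_lu, arm.p_le, "active")
    mid = transform_point(arm.t_es, inner, "active")
    return transform_point(arm.r_ub, mid, "active")


def _comm(p_dq, omega) -> np.ndarray:
    """½(P Ω − Ω P): the ω⃗ × r⃗ term of a rotating point, as a velocity DQ."""
    om = dq_from_quat(pure(np.asarray(omega, dtype=float)))
    return 0.5 * (dqmul(p_dq, om) - dqmul(om, p_dq))


def twolink_fk_velocity(arm: TwoLinkArm, omega_ub, omega_lu) -> np.ndarray:
    """End-effector velocity (3-vector, cm/s) for given joint rotational velocities.

    ``omega_ub`` is the shoulder rotational velocity in body coordinates,
    ``omega_lu`` the elbow one in upper-arm coordinates (rad/s).
    """
    p_bs = twolink_fk_position(arm)
    p_ue = twolink_hand_in_upper(arm)
    term_shoulder = _comm(p_bs, omega_ub)
    elbow_comm = _comm(p_ue, omega_lu)
    r = arm.r_ub
    term_elbow = dqmul(dqconj(r, "quaternion"), dqmul(elbow_comm, r))
    return decode_velocity(term_shoulder + term_elbow)


# ---------------------------------------------------------------------------
# three-link arm
# ---------------------------------------------------------------------------


@dataclass
class ThreeLinkArm:
    """Three-link arm (upper arm a, forearm b, hand/tool c, cm) with 7 dof.

    Joint rotations: shoulder ``r_ub`` (3 dof), elbow ``r_lu`` (1 dof about
    ``n_lu``, default z), wrist ``r_hl`` (3 dof).  Axes of the elbow and
    wrist rotations are expressed in the parent link's frame.
    """

    a: float = 30.0
    b: float = 30.0
    c: float = 15.0
    r_ub: np.ndarray = field(default_factory=lambda: make_rotation(RotationSpec(N_ELBOW, 0.0)))
    r_lu: np.ndarray = field(default_factory=lambda: make_rotation(RotationSpec(N_ELBOW, 0.0)))
    r_hl: np.ndarray = field(default_factory=lambda: make_rotation(RotationSpec(N_ELBOW, 0.0)))
    n_lu: np.ndarray = field(default_factory=lambda: N_ELBOW.copy())

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise UsageError("link lengths must be positive")
        self.r_ub = _as_rot_dq(self.r_ub)
        self.r_lu = _as_rot_dq(self.r_lu)
        self.r_hl = _as_rot_dq(self.r_hl)
        self.n_lu = np.asarray(self.n_lu, dtype=float)

    @property
    def reference_point(self) -> np.ndarray:
        return np.array([self.a + self.b + self.c, 0.0, 0.0])

    @property
    def reference_line(self) -> np.ndarray:
        return encode_line([0.0, 1.0, 0.0], self.reference_point)


def threelink_screws(arm: ThreeLinkArm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The three joint screw operators (S_UB, S_LU, S_HL)."""
    t_es = translation_from_vector([arm.a, 0.0, 0.0])
    t_ws = translation_from_vector([arm.a + arm.b, 0.0, 0.0])
    s_ub = arm.r_ub
    s_lu = dqmul(dqconj(t_es, "quaternion"), dqmul(arm.r_lu, t_es))
    s_hl = dqmul(dqconj(t_ws, "quaternion"), dqmul(arm.r_hl, t_ws))
    return s_ub, s_lu, s_hl


def _s_tot(arm: ThreeLinkArm) -> np.ndarray:
    s_ub, s_lu, s_hl = threelink_screws(arm)
    return dqmul(s_hl, dqmul(s_lu, s_ub))


def threelink_line_fk(arm: ThreeLinkArm) -> np.ndarray:
    """End-effector line DQ in BS coordinates: ``L = S_tot* L₀ S_tot``."""
    return transform_line(_s_tot(arm), arm.reference_line, "active")


def threelink_point_fk(arm: ThreeLinkArm) -> np.ndarray:
    """End-effector point DQ in BS coordinates (mixed-conjugate sandwich).

    The line alone determines position only orthogonally to its direction;
    the point transform supplies the along-line component.
    """
    return transform_point(_s_tot(arm), encode_point(arm.reference_point), "active")


def _screw_rates(arm: ThreeLinkArm, omega_ub, omega_lu, omega_hl):
    """Ṡ for each joint screw: only the rotation moves, so Ṡ = ½ T_L* R Ω T_L."""
    t_es = translation_from_vector([arm.a, 0.0, 0.0])
    t_ws = translation_from_vector([arm.a + arm.b, 0.0, 0.0])
    rates = []
    for r, t_l, om in (
        (arm.r_ub, None, omega_ub),
        (arm.r_lu, t_es, omega_lu),
        (arm.r_hl, t_ws, omega_hl),
    ):
        om_dq = dq_from_quat(pure(np.asarray(om, dtype=float)))
        core = 0.5 * dqmul(r, om_dq)
        if t_l is None:
            rates.append(core)
        else:
            rates.append(dqmul(dqconj(t_l, "quaternion"), dqmul(core, t_l)))
    return rates


def threelink_line_rate(arm: ThreeLinkArm, omega_ub, omega_lu, omega_hl) -> np.ndarray:
    """End-effector line velocity DQ (ṅ + ε ṁ) by the product rule on the screw chain.

    Four groups of terms: the (zero, here) reference-line rate transported
    through the whole chain, then one commutator-like pair per joint with
    the partially transformed lines L_w (after the wrist) and L_e (after
    the elbow) as the moving entities.
    """
    s_ub, s_lu, s_hl = threelink_screws(arm)
    sd_ub, sd_lu, sd_hl = _screw_rates(arm, omega_ub, omega_lu, omega_hl)
    l0 = arm.reference_line
    qc = lambda d: dqconj(d, "quaternion")

    l_w = dqmul(qc(s_hl), dqmul(l0, s_hl))
    l_e = dqmul(qc(s_lu), dqmul(l_w, s_lu))

    wrist = dqmul(qc(sd_hl), dqmul(l0, s_hl)) + dqmul(qc(s_hl), dqmul(l0, sd_hl))
    wrist = dqmul(qc(s_ub), dqmul(qc(s_lu), dqmul(wrist, dqmul(s_lu, s_ub))))
    elbow = dqmul(qc(sd_lu), dqmul(l_w, s_lu)) + dqmul(qc(s_lu), dqmul(l_w, sd_lu))
    elbow = dqmul(qc(s_ub), dqmul(elbow, s_ub))
    shoulder = dqmul(qc(sd_ub), dqmul(l_e, s_ub)) + dqmul(qc(s_ub), dqmul(l_e, sd_ub))
    return wrist + elbow + shoulder


def threelink_point_rate(arm: ThreeLinkArm, omega_ub, omega_lu, omega_hl) -> np.ndarray:
    """End-effector point velocity (3-vector, cm/s): product rule with the mixed conjugate."""
    s_ub, s_lu, s_hl = threelink_screws(arm)
    sd_ub, sd_lu, sd_hl = _screw_rates(arm, omega_ub, omega_lu, omega_hl)
    p0 = encode_point(arm.reference_point)
    mc = lambda d: dqconj(d, "mixed")

    p_w = dqmul(mc(s_hl), dqmul(p0, s_hl))
    p_e = dqmul(mc(s_lu), dqmul(p_w, s_lu))

    wrist = dqmul(mc(sd_hl), dqmul(p0, s_hl)) + dqmul(mc(s_hl), dqmul(p0, sd_hl))
    wrist = dqmul(mc(s_ub), dqmul(mc(s_lu), dqmul(wrist, dqmul(s_lu, s_ub))))
    elbow = dqmul(mc(sd_lu), dqmul(p_w, s_lu)) + dqmul(mc(s_lu), dqmul(p_w, sd_lu))
    elbow = dqmul(mc(s_ub), dqmul(elbow, s_ub))
    shoulder = dqmul(mc(sd_ub), dqmul(p_e, s_ub)) + dqmul(mc(s_ub), dqmul(p_e, sd_ub))
    return decode_velocity(wrist + elbow + shoulder)
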