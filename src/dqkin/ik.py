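"""Differential inverse kinematics with a closed-loop pseudo-inverse solver.

The task Jacobians come straight from the dual-quaternion velocity
formulas: the commutator ``½(P Ω − Ω P) = −ε(P⃗ ∧ Ω⃗)`` turns each joint
contribution into a cross-product matrix, so for the two-link arm

    Ṗ_BS = −(Ã_P_BS   R_UB Ã_P_UE) · (Ω_UB; Ω_LU)

where ``Ã_a`` is the antisymmetric (rank-2) matrix of a⃗× and R_UB the
shoulder rotation matrix.  The one-dof elbow constraint
``n_elbow × Ω_LU = 0`` is appended as extra rows, giving a 6×6 system of
generic rank 5: the one-dimensional kernel is the arm's self-rotation
about the shoulder–hand axis.

The redundant system is solved with the Moore–Penrose pseudo-inverse
(SVD, relative cutoff 1e-10): ``x = J⁺ rhs`` is the minimal-norm joint
velocity, and ``x + (I − J⁺J) w`` parameterizes all solutions.  Joint
rotations are advanced by explicit Euler with renormalization
(``R ← (R + ½ R Ω Δt)/‖·‖``) or by the exponential map (``R ← R·ΔR``
with ΔR the rotation by ‖Ω‖Δt); drift of the integrated joints away
from the commanded path is cancelled by feeding back the position error
``e = P_des − FK(joints)`` with gain K = k₁·I.  The scalar error
recursion ``e⁺ = (1 − k₁Δt)e`` bounds the usable gain at ``k₁ < 2/Δt``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import (
    N_ELBOW,
    ThreeLinkArm,
    TwoLinkArm,
    threelink_line_fk,
    threelink_point_fk,
    threelink_line_rate,
    threelink_point_rate,
    twolink_fk_position,
    twolink_fk_velocity,
    twolink_hand_in_upper,
)
from .entities import decode_point, line_direction
from .errors import DivergenceError, UsageError
from .fixtures import Trajectory
from .quat import qconj, qmul, qnorm, qvec
from .rigid import _rot_quat  # axis-angle quaternion for the exponential map

__all__ = [
    "JacobianBundle",
    "CLIKConfig",
    "IKResult",
    "cross_matrix",
    "rotation_matrix",
    "planar_jacobian",
    "spatial_jacobian",
    "constrained_jacobian",
    "threelink_task_jacobian",
    "solve_joint_rates",
    "integrate_step",
    "clik_track",
    "threelink_clik_track",
    "max_stable_gain",
    "error_recursion",
]

SV_CUTOFF = 1e-10


def cross_matrix(a) -> np.ndarray:
    """Antisymmetric matrix Ã of a⃗ with ``Ã x = a⃗ × x``; rank 2 for a ≠ 0."""
    a1, a2, a3 = np.asarray(a, dtype=float)
    return np.array([[0.0, -a3, a2], [a3, 0.0, -a1], [-a2, a1, 0.0]])


def rotation_matrix(r) -> np.ndarray:
    """3×3 matrix of the active sandwich ``x ↦ R* x R`` of a rotation (dual) quaternion."""
    r = np.asarray(r, dtype=float)
    q = r[:4] if r.shape == (8,) else r
    cols = [qvec(qmul(qconj(q), qmul(np.concatenate([[0.0], e]), q))) for e in np.eye(3)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class JacobianBundle:
    """A task Jacobian with its pseudo-inverse and redundancy structure.

    ``j_dq`` stacks the velocity dual quaternions the columns were
    extracted from (8×k, when available); ``nullspace`` is the projector
    I − J⁺J onto the self-motion manifold.
    """

    j: np.ndarray
    j_plus: np.ndarray
    rank: int
    nullspace: np.ndarray
    j_dq: np.ndarray | None = None

    @classmethod
    def from_matrix(cls, j: np.ndarray, j_dq: np.ndarray | None = None, cutoff: float = SV_CUTOFF) -> "JacobianBundle":
        j = np.asarray(j, dtype=float)
        j_plus = np.linalg.pinv(j, rcond=cutoff)
        sv = np.linalg.svd(j, compute_uv=False)
        rank = int(np.sum(sv > cutoff * sv[0])) if sv[0] > 0 else 0
        return cls(j=j, j_plus=j_plus, rank=rank, nullspace=np.eye(j.shape[1]) - j_plus @ j, j_dq=j_dq)


def _plane_basis(n: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane ⟂ n (rows of a 2×3 matrix)."""
    n = np.asarray(n, dtype=float)
    helper = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = helper - np.dot(helper, n) * n
    e1 /= np.linalg.norm(e1)
    return np.vstack([e1, np.cross(n, e1)])


def planar_jacobian(arm: TwoLinkArm, n=N_ELBOW) -> JacobianBundle:
    """2×2 Jacobian of the planar two-dof arm (both joints rotate about ``n``).

    Columns are the in-plane components of the two joint velocity dual
    quaternions (unit rates φ̇ = 1 and θ̇ = 1).  Singular exactly when the
    arm is aligned (θ = 0 or 180°): rank drops to 1.
    """
    n = np.asarray(n, dtype=float)
    cols_3d = [
        twolink_fk_velocity(arm, n, np.zeros(3)),
        twolink_fk_velocity(arm, np.zeros(3), n),
    ]
    basis = _plane_basis(n)
    j = np.column_stack([basis @ c for c in cols_3d])
    return JacobianBundle.from_matrix(j)


def spatial_jacobian(arm: TwoLinkArm) -> JacobianBundle:
    """3×6 Jacobian mapping (Ω_UB; Ω_LU) to the end-effector velocity.

    ``J = −(Ã_P_BS   R_UB Ã_P_UE)`` with the leading minus from the
    commutator identity; validated against the FK velocity formula.
    """
    p_bs = decode_point(twolink_fk_position(arm))
    p_ue = decode_point(twolink_hand_in_upper(arm))
    r_m = rotation_matrix(arm.r_ub)
    j = -np.hstack([cross_matrix(p_bs), r_m @ cross_matrix(p_ue)])
    return JacobianBundle.from_matrix(j)


def constrained_jacobian(arm: TwoLinkArm, n_elbow=N_ELBOW) -> JacobianBundle:
    """6×6 Jacobian: task rows plus the elbow-axis constraint ``n_elbow × Ω_LU = 0``.

    Generic rank is 5; the kernel is the self-rotation of the arm about
    the shoulder–end-effector axis.
    """
    top = spatial_jacobian(arm).j
    bottom = np.hstack([np.zeros((3, 3)), cross_matrix(n_elbow)])
    return JacobianBundle.from_matrix(np.vstack([top, bottom]))


def threelink_task_jacobian(arm: ThreeLinkArm) -> JacobianBundle:
    """9×9 Jacobian of the three-link arm: point velocity, line-direction rate,
    and the elbow-axis constraint rows, over (Ω_UB; Ω_LU; Ω_HL).

    Columns are evaluated from the analytic point/line rate formulas at
    unit joint rates (the task map is linear in the Ω's).
    """
    # evaluate all nine columns in one batched pass: column j is the task
    # velocity at unit rate of joint-axis component j
    om = [np.zeros((3, 9)) for _ in range(3)]
    for block in range(3):
        om[block][:, 3 * block : 3 * block + 3] = np.eye(3)
    v = threelink_point_rate(arm, *om)
    ndot = qvec(threelink_line_rate(arm, *om)[:4])
    task = np.vstack([v, ndot])
    constraint = np.hstack([np.zeros((3, 3)), cross_matrix(arm.n_lu), np.zeros((3, 3))])
    return JacobianBundle.from_matrix(np.vstack([task, constraint]))


def solve_joint_rates(bundle: JacobianBundle, rhs, w=None) -> np.ndarray:
    """Minimal-norm (least-squares) joint rates ``x = J⁺ rhs + (I − J⁺J) w``."""
    rhs = np.asarray(rhs, dtype=float)
    if rhs.shape[0] != bundle.j.shape[0]:
        raise UsageError(f"rhs has dimension {rhs.shape[0]}, Jacobian has {bundle.j.shape[0]} rows")
    x = bundle.j_plus @ rhs
    if w is not None:
        x = x + bundle.nullspace @ np.asarray(w, dtype=float)
    return x


INTEGRATORS = ("euler_renorm", "exp_map")


def integrate_step(r, omega, dt: float, method: str = "euler_renorm") -> np.ndarray:
    """Advance a rotation (dual) quaternion one step under rotational velocity Ω.

    ``euler_renorm``: ``R ← (R + ½ R Ω Δt) / ‖·‖`` — the explicit Euler
    step of ``Ṙ = ½ R Ω`` followed by renormalization.
    ``exp_map``: ``R ← R·ΔR`` with ΔR the exact rotation by the angular
    vector ΩΔt; exactly unit by construction.  The two agree to O(Δt²).
    """
    r = np.asarray(r, dtype=float)
    q = r[:4] if r.shape == (8,) else r
    omega = np.asarray(omega, dtype=float)
    if method == "euler_renorm":
        qdot = 0.5 * qmul(q, np.concatenate([[0.0], omega]))
        qn = q + qdot * dt
        qn = qn / qnorm(qn)
    elif method == "exp_map":
        angle = float(np.linalg.norm(omega)) * dt
        axis = omega / np.linalg.norm(omega) if angle > 0 else np.array([0.0, 0.0, 1.0])
        qn = qmul(q, _rot_quat(axis, angle))
    else:
        raise UsageError(f"unknown integrator {method!r}; expected one of {INTEGRATORS}")
    if r.shape == (8,):
        return np.concatenate([qn, np.zeros(4)])
    return qn


@dataclass(frozen=True)
class CLIKConfig:
    """Closed-loop IK parameters: feedback gain k₁ (1/s), timestep Δt (s),
    integrator, and optional nullspace vector w."""

    k1: float = 1000.0
    dt: float = 1e-3
    integrator: str = "euler_renorm"
    w: np.ndarray | None = None
    sv_cutoff: float = SV_CUTOFF

    def __post_init__(self):
        if self.dt <= 0:
            raise UsageError("dt must be positive")
        if self.integrator not in INTEGRATORS:
            raise UsageError(f"unknown integrator {self.integrator!r}")
        if self.k1 < 0:
            raise UsageError("gain k1 must be nonnegative")

    @property
    def stable(self) -> bool:
        return self.k1 < max_stable_gain(self.dt)


@dataclass(frozen=True)
class IKResult:
    """Joint and error time series from a closed-loop IK run.

    ``r_ub``/``r_lu`` (and ``r_hl`` for three links) are 4×N quaternion
    series; ``omega`` stacks the solved joint rates; ``errors`` is the
    per-step ‖e(t)‖ in cm (for line tasks ``direction_errors`` adds the
    orientation error in radians); ``ranks`` records the per-step
    numerical rank of the task Jacobian.
    """

    t: np.ndarray
    r_ub: np.ndarray
    r_lu: np.ndarray
    omega: np.ndarray
    errors: np.ndarray
    ranks: np.ndarray
    r_hl: np.ndarray | None = None
    direction_errors: np.ndarray | None = None

    @property
    def max_error(self) -> float:
        return float(np.max(self.errors))


def max_stable_gain(dt: float) -> float:
    """Largest stable feedback gain for timestep Δt: k_max = 2/Δt.

    From the scalar error recursion ``e⁺ = (1 − k₁Δt)e``, non-divergent
    iff ``|1 − k₁Δt| ≤ 1``.
    """
    if dt <= 0:
        raise UsageError("dt must be positive")
    return 2.0 / dt


def error_recursion(k1: float, dt: float, e0: float = 1.0, n_steps: int = 200) -> np.ndarray:
    """Simulate the scalar closed-loop error recursion ``e⁺ = (1 − k₁Δt)e``."""
    factor = 1.0 - k1 * dt
    return e0 * factor ** np.arange(n_steps + 1)


def clik_track(arm: TwoLinkArm, trajectory: Trajectory, cfg: CLIKConfig | None = None) -> IKResult:
    """Track an end-effector trajectory with the four-dof two-link arm.

    Per step: assemble the constrained 6×6 Jacobian at the current joints,
    solve ``J·(Ω) = (Ṗ_des + k₁ e; 0)`` by pseudo-inverse, and integrate
    the two joint rotations.  The commanded trajectory must start at the
    arm's current end-effector position.  If the error exceeds the
    workspace diameter the run aborts with a diagnostic.
    """
    cfg = cfg or CLIKConfig()
    if not cfg.stable:
        import warnings

        warnings.warn(
            f"gain k1={cfg.k1:g} exceeds the stability bound 2/dt={max_stable_gain(cfg.dt):g}; expect divergence",
            stacklevel=2,
        )
    n = trajectory.pos.shape[1]
    r_ub, r_lu = arm.r_ub.copy(), arm.r_lu.copy()
    # an error the size of the reach radius can only mean the loop blew up
    workspace = arm.a + arm.b

    r_ub_s = np.zeros((4, n))
    r_lu_s = np.zeros((4, n))
    omegas = np.zeros((6, n))
    errors = np.zeros(n)
    ranks = np.zeros(n, dtype=int)

    for i in range(n):
        state = TwoLinkArm(arm.a, arm.b, r_ub, r_lu)
        p_hat = decode_point(twolink_fk_position(state))
        e = trajectory.pos[:, i] - p_hat
        errors[i] = np.linalg.norm(e)
        r_ub_s[:, i], r_lu_s[:, i] = r_ub[:4], r_lu[:4]
        if errors[i] > workspace:
            raise DivergenceError(
                f"closed-loop IK diverged at t={trajectory.t[i]:.4g}s (‖e‖={errors[i]:.3g} cm exceeds workspace)"
            )
        bundle = constrained_jacobian(state)
        ranks[i] = bundle.rank
        rhs = np.concatenate([trajectory.vel[:, i] + cfg.k1 * e, np.zeros(3)])
        x = solve_joint_rates(bundle, rhs, cfg.w)
        omegas[:, i] = x
        r_ub = integrate_step(r_ub, x[:3], cfg.dt, cfg.integrator)
        r_lu = integrate_step(r_lu, x[3:], cfg.dt, cfg.integrator)

    return IKResult(t=trajectory.t, r_ub=r_ub_s, r_lu=r_lu_s, omega=omegas, errors=errors, ranks=ranks)


def threelink_clik_track(
    arm: ThreeLinkArm,
    t: np.ndarray,
    pos: np.ndarray,
    vel: np.ndarray,
    direction: np.ndarray,
    direction_rate: np.ndarray,
    cfg: CLIKConfig | None = None,
) -> IKResult:
    """Track a point + line-direction task with the seven-dof three-link arm.

    ``pos``/``vel`` are 3×N end-effector point series, ``direction`` /
    ``direction_rate`` the desired tool-line direction and its rate.  The
    orientation error uses the axis ``n × n_des`` (zero iff aligned), the
    standard small-angle attitude error.
    """
    cfg = cfg or CLIKConfig()
    n = pos.shape[1]
    r_ub, r_lu, r_hl = arm.r_ub.copy(), arm.r_lu.copy(), arm.r_hl.copy()

    r_ub_s, r_lu_s, r_hl_s = (np.zeros((4, n)) for _ in range(3))
    omegas = np.zeros((9, n))
    errors = np.zeros(n)
    dir_errors = np.zeros(n)
    ranks = np.zeros(n, dtype=int)
    workspace = arm.a + arm.b + arm.c

    for i in range(n):
        state = ThreeLinkArm(arm.a, arm.b, arm.c, r_ub, r_lu, r_hl, arm.n_lu)
        p_hat = decode_point(threelink_point_fk(state))
        n_hat = line_direction(threelink_line_fk(state))
        e_p = pos[:, i] - p_hat
        n_des = direction[:, i]
        # tangent-plane attitude error: vanishes iff n_hat ∥ n_des and is the
        # direction ṅ must take to close the angle
        e_n = np.cross(np.cross(n_hat, n_des), n_hat)
        errors[i] = np.linalg.norm(e_p)
        dir_errors[i] = float(np.arccos(np.clip(np.dot(n_hat, n_des), -1.0, 1.0)))
        r_ub_s[:, i], r_lu_s[:, i], r_hl_s[:, i] = r_ub[:4], r_lu[:4], r_hl[:4]
        if errors[i] > workspace:
            raise DivergenceError(f"three-link closed-loop IK diverged at step {i} (‖e‖={errors[i]:.3g} cm)")
        bundle = threelink_task_jacobian(state)
        ranks[i] = bundle.rank
        rhs = np.concatenate([vel[:, i] + cfg.k1 * e_p, direction_rate[:, i] + cfg.k1 * e_n, np.zeros(3)])
        x = solve_joint_rates(bundle, rhs, cfg.w)
        omegas[:, i] = x
        r_ub = integrate_step(r_ub, x[:3], cfg.dt, cfg.integrator)
        r_lu = integrate_step(r_lu, x[3:6], cfg.dt, cfg.integrator)
        r_hl = integrate_step(r_hl, x[6:], cfg.dt, cfg.integrator)

    return IKResult(
        t=np.asarray(t),
        r_ub=r_ub_s,
        r_lu=r_lu_s,
        omega=omegas,
        errors=errors,
        ranks=ranks,
        r_hl=r_hl_s,
        direction_errors=dir_errors,
    )
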