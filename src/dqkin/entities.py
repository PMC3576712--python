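"""Points and Plücker lines as dual quaternions, and the unified sandwich transforms.

A point at x⃗ is ``X = 1 + ε x``; a line with unit direction n⃗ through a
point p⃗ is ``L = n + ε m`` with moment ``m = p⃗ ∧ n⃗`` (independent of the
choice of p⃗ on the line).  Both are transformed by the *same* unit
dual-quaternion sandwich; the only difference is the conjugate used —
the mixed conjugate ``D̄*`` for points and the quaternion conjugate
``D*`` for lines.  :func:`transform` dispatches on the entity kind so
that conjugate choice lives in exactly one place.

Modes: ``"passive"`` re-expresses a fixed entity in a displaced frame
(``D X D̄*``); ``"active"`` displaces a mobile entity in a fixed frame
(``D̄* X D``).  For rotations the two modes are mutually inverse
(R* X R vs R X R*).  For translations the mixed conjugate equals the
operator itself (T̄* = T), so *both* modes displace by +d·t — inverting
a translation means negating its distance, not switching mode.  Kinematic
chains therefore read identically in either direction, which is exactly
why the chain formulas in :mod:`dqkin.visuomotor` and :mod:`dqkin.arm`
can alternate rotations and translations freely.
"""

from __future__ import annotations

import numpy as np

from .errors import DQKinError, NonUnitError, UsageError
from .quat import (
    dq,
    dqconj,
    dqmul,
    pure,
    qvec,
    unit_residuals,
)
from .rigid import unit_axis

__all__ = [
    "encode_point",
    "decode_point",
    "point_velocity_dq",
    "decode_velocity",
    "encode_line",
    "decode_line",
    "line_direction",
    "line_moment",
    "line_rate_from_point",
    "transform",
    "transform_point",
    "transform_line",
    "transformed_point_rate",
    "transformed_line_rate",
]

_MODES = ("passive", "active")


def encode_point(x) -> np.ndarray:
    """Point dual quaternion ``X = 1 + ε x`` (columns-are-points for a 3×N batch)."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != 3:
        raise UsageError(f"point coordinates must be (3,) or (3, N), got {x.shape}")
    real = np.zeros((4,) + x.shape[1:])
    real[0] = 1.0
    return dq(real, pure(x))


def decode_point(x_dq, tol: float = 1e-6) -> np.ndarray:
    """Extract x⃗ from a point dual quaternion, checking the ``1 + ε x`` structure."""
    x_dq = np.asarray(x_dq, dtype=float)
    resid = max(
        float(np.max(np.abs(x_dq[0] - 1.0))),
        float(np.max(np.abs(x_dq[1:4]))),
        float(np.max(np.abs(x_dq[4]))),
    )
    if resid > tol:
        raise DQKinError(f"not a point dual quaternion (structure residual {resid:.3g})")
    return x_dq[5:]


def point_velocity_dq(xdot) -> np.ndarray:
    """Velocity dual quaternion ``V = ε ẋ``."""
    xdot = np.asarray(xdot, dtype=float)
    return dq(np.zeros((4,) + xdot.shape[1:]), pure(xdot))


def decode_velocity(v_dq, tol: float = 1e-6) -> np.ndarray:
    """Extract ẋ from a velocity dual quaternion ``ε ẋ``, checking structure."""
    v_dq = np.asarray(v_dq, dtype=float)
    resid = max(float(np.max(np.abs(v_dq[:4]))), float(np.max(np.abs(v_dq[4]))))
    if resid > tol:
        raise DQKinError(f"not a velocity dual quaternion (structure residual {resid:.3g})")
    return v_dq[5:]


# ---------------------------------------------------------------------------
# lines
# ---------------------------------------------------------------------------


def encode_line(n, p) -> np.ndarray:
    """Line dual quaternion ``L = n + ε (p⃗ ∧ n⃗)`` from unit direction and a point on the line."""
    n = unit_axis(n, what="line direction")
    p = np.asarray(p, dtype=float)
    return dq(pure(n), pure(np.cross(p, n)))


def line_direction(line) -> np.ndarray:
    return qvec(np.asarray(line, dtype=float)[:4])


def line_moment(line) -> np.ndarray:
    return qvec(np.asarray(line, dtype=float)[4:])


def decode_line(line, tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Extract ``(n, p_closest)`` with p_closest = n⃗ × m⃗ the axis point nearest the origin.

    The closest-point tie-break makes decoding deterministic; any other
    point ``p_closest + λ n`` encodes the same line.
    """
    line = np.asarray(line, dtype=float)
    n, m = line_direction(line), line_moment(line)
    if abs(np.linalg.norm(n) - 1.0) > tol or abs(float(np.dot(n, m))) > tol:
        raise DQKinError("invalid line dual quaternion (unit-direction or Plücker constraint violated)")
    if max(abs(float(line[0])), abs(float(line[4]))) > tol:
        raise DQKinError("invalid line dual quaternion (nonzero scalar parts)")
    return n, np.cross(n, m)


def line_rate_from_point(n, ndot, p, pdot) -> np.ndarray:
    """Line-velocity dual quaternion ``L̇ = ṅ + ε(ṗ⃗ ∧ n⃗ + p⃗ ∧ ṅ⃗)``.

    Independent of which point/rate pair on the moving line is supplied.
    """
    n, ndot = np.asarray(n, float), np.asarray(ndot, float)
    p, pdot = np.asarray(p, float), np.asarray(pdot, float)
    return dq(pure(ndot), pure(np.cross(pdot, n) + np.cross(p, ndot)))


# ---------------------------------------------------------------------------
# sandwich transforms
# ---------------------------------------------------------------------------


def _require_unit(d, tol: float) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    r1, r2 = unit_residuals(d)
    if np.any(np.abs(r1) > tol) or np.any(np.abs(r2) > tol):
        raise NonUnitError(
            f"operator is not a unit dual quaternion (residuals {np.max(np.abs(r1)):.3g}, {np.max(np.abs(r2)):.3g})"
        )
    return d


def _conj_for(kind: str) -> str:
    # points use the mixed conjugate, lines the quaternion conjugate
    if kind == "point":
        return "mixed"
    if kind == "line":
        return "quaternion"
    raise UsageError(f"unknown entity kind {kind!r}; expected 'point' or 'line'")


def transform(d, entity, kind: str, mode: str = "active", tol: float = 1e-6) -> np.ndarray:
    """Apply a unit dual quaternion to a point or line dual quaternion.

    passive: ``X' = D X D^``   active: ``X' = D^ X D``
    where ``D^`` is the entity-appropriate conjugate (see module docstring).
    """
    if mode not in _MODES:
        raise UsageError(f"unknown mode {mode!r}; expected one of {_MODES}")
    d = _require_unit(d, tol)
    entity = np.asarray(entity, dtype=float)
    dc = dqconj(d, _conj_for(kind))
    if mode == "passive":
        return dqmul(d, dqmul(entity, dc))
    return dqmul(dc, dqmul(entity, d))


def transform_point(d, x_dq, mode: str = "active", tol: float = 1e-6) -> np.ndarray:
    """Sandwich-transform a point dual quaternion (mixed conjugate)."""
    out = transform(d, x_dq, "point", mode, tol)
    # rigid sandwiches keep the 1 + ε x structure exactly (up to round-off)
    decode_point(out, tol=1e-6)
    return out


def transform_line(d, line, mode: str = "active", tol: float = 1e-6) -> np.ndarray:
    """Sandwich-transform a line dual quaternion (quaternion conjugate)."""
    return transform(d, line, "line", mode, tol)


def _conj_rate(ddot, kind: str) -> np.ndarray:
    return dqconj(np.asarray(ddot, dtype=float), kind)


def transformed_point_rate(d, ddot, x_dq, v_dq=None, mode: str = "active", tol: float = 1e-6) -> np.ndarray:
    """Velocity of a transformed point by the product rule on the sandwich.

    active:  ``Ṗ = Ḋ̄* X D + D̄* Ẋ D + D̄* X Ḋ``
    passive: ``V' = Ḋ X D̄* + D Ẋ D̄* + D X Ḋ̄*``

    Covers the rotating-frame, translating-frame and screw special cases;
    with a pure rotation it reduces to the commutator form
    ``½(P Ω − Ω P) + R* Ṗ₀ R`` (the classic ω⃗ × r⃗ term).
    """
    if mode not in _MODES:
        raise UsageError(f"unknown mode {mode!r}; expected one of {_MODES}")
    d = _require_unit(d, tol)
    ddot = np.asarray(ddot, dtype=float)
    x_dq = np.asarray(x_dq, dtype=float)
    v_dq = np.zeros_like(x_dq) if v_dq is None else np.asarray(v_dq, dtype=float)
    dc, dcdot = dqconj(d, "mixed"), _conj_rate(ddot, "mixed")
    if mode == "passive":
        out = dqmul(ddot, dqmul(x_dq, dc)) + dqmul(d, dqmul(v_dq, dc)) + dqmul(d, dqmul(x_dq, dcdot))
    else:
        out = dqmul(dcdot, dqmul(x_dq, d)) + dqmul(dc, dqmul(v_dq, d)) + dqmul(dc, dqmul(x_dq, ddot))
    decode_velocity(out, tol=1e-6)
    return out


def transformed_line_rate(d, ddot, line, line_dot=None, mode: str = "active", tol: float = 1e-6) -> np.ndarray:
    """Velocity of a transformed line: ``L̇ = Ḋ* L₀ D + D* L₀ Ḋ + D* L̇₀ D`` (active).

    The result is again of line-velocity form ṅ + ε ṁ with ṅ ⟂ n.
    """
    if mode not in _MODES:
        raise UsageError(f"unknown mode {mode!r}; expected one of {_MODES}")
    d = _require_unit(d, tol)
    ddot = np.asarray(ddot, dtype=float)
    line = np.asarray(line, dtype=float)
    line_dot = np.zeros_like(line) if line_dot is None else np.asarray(line_dot, dtype=float)
    dc, dcdot = dqconj(d, "quaternion"), _conj_rate(ddot, "quaternion")
    if mode == "passive":
        return dqmul(ddot, dqmul(line, dc)) + dqmul(d, dqmul(line_dot, dc)) + dqmul(d, dqmul(line, dcdot))
    return dqmul(dcdot, dqmul(line, d)) + dqmul(dc, dqmul(line_dot, d)) + dqmul(dc, dqmul(line, ddot))
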