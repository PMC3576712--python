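"""Quaternion and dual-quaternion geometric algebra.

A quaternion ``Q = q0 + i q⃗`` (scalar plus bivector part) is stored as a
4-vector ``[q0, qx, qy, qz]``; a dual quaternion ``D = D0 + ε D1`` (ε² = 0)
as an 8-vector ``[D0, D1]``.  Every operation accepts either a single
element of shape ``(4,)`` / ``(8,)`` or a batch of N elements stored as
columns of a ``(4, N)`` / ``(8, N)`` array, and broadcasting a single
element against a batch is allowed.  This columns-are-elements layout is
the library-wide serialization contract.

Multiplication sign convention
------------------------------
The product implemented here is the geometric (bivector) product

    ``AB = (a0·b0 − a⃗·b⃗) + i(a0 b⃗ + b0 a⃗ − a⃗×b⃗)``

with a **minus** sign on the cross-product term.  This is the mirror of
the Hamilton ``ij = k`` convention (it equals the Hamilton product with
the factors swapped).  All sandwich operators downstream are validated
against geometric oracles under this convention; do not mix routines
from Hamilton-convention libraries into these chains.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import SingularElementError, UsageError

#: default absolute tolerance for equality / unitarity checks
DEFAULT_TOL = 1e-9

__all__ = [
    "DEFAULT_TOL",
    "DualNumber",
    "qidentity",
    "quat",
    "qscalar",
    "qvec",
    "pure",
    "qmul",
    "qconj",
    "qnorm",
    "qinv",
    "dq",
    "dq_identity",
    "dq_real",
    "dq_dual",
    "dq_from_quat",
    "dqmul",
    "dqconj",
    "dqnorm",
    "dqinv",
    "is_unit",
    "unit_residuals",
]


class DualNumber(NamedTuple):
    """Dual number ``a = a0 + ε a1``; the norm of a dual quaternion is one.

    When the real part of a dual quaternion has zero norm its dual norm
    component is undefined; it is then reported as ``nan`` and
    :attr:`is_defined` is False (such elements admit no inverse).
    """

    a0: float | np.ndarray
    a1: float | np.ndarray

    @property
    def is_defined(self) -> bool | np.ndarray:
        return ~np.isnan(np.asarray(self.a1)) if np.ndim(self.a1) else not np.isnan(self.a1)


def _asq(a, rows: int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape[0] != rows or a.ndim > 2:
        raise UsageError(f"expected a ({rows},) or ({rows}, N) array, got shape {a.shape}")
    return a


def quat(q0, qv) -> np.ndarray:
    """Assemble a quaternion (or batch) from scalar part and bivector coordinates."""
    qv = np.asarray(qv, dtype=float)
    if qv.shape[0] != 3:
        raise UsageError(f"expected a (3,) or (3, N) vector part, got shape {qv.shape}")
    q0 = np.broadcast_to(np.asarray(q0, dtype=float), qv.shape[1:])
    return np.concatenate([q0[None, ...], qv], axis=0)


def qidentity(n: int | None = None) -> np.ndarray:
    """Identity quaternion ``1 + i·0`` (optionally a batch of n copies)."""
    if n is None:
        return np.array([1.0, 0.0, 0.0, 0.0])
    out = np.zeros((4, n))
    out[0] = 1.0
    return out


def pure(v) -> np.ndarray:
    """Pure-bivector quaternion ``0 + i v⃗`` from 3-vector coordinates (or 3×N batch)."""
    v = np.asarray(v, dtype=float)
    if v.shape[0] != 3:
        raise UsageError(f"expected a (3,) or (3, N) array, got shape {v.shape}")
    zeros = np.zeros(v.shape[1:])
    return np.concatenate([zeros[None, ...], v], axis=0)


def qscalar(a) -> np.ndarray | float:
    return _asq(a, 4)[0]


def qvec(a) -> np.ndarray:
    """Bivector coordinates (3-vector or 3×N)."""
    return _asq(a, 4)[1:]


def _align(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Broadcast a single element against a batch (columns are elements)."""
    if a.ndim == 1 and b.ndim == 2:
        a = a[:, None]
    elif a.ndim == 2 and b.ndim == 1:
        b = b[:, None]
    return a, b


def qmul(a, b) -> np.ndarray:
    """Geometric product of two quaternions (see module docstring for the sign convention)."""
    a, b = _align(_asq(a, 4), _asq(b, 4))
    a0, av = a[0], a[1:]
    b0, bv = b[0], b[1:]
    c0 = a0 * b0 - np.sum(av * bv, axis=0)
    cv = a0 * bv + b0 * av - np.cross(av, bv, axisa=0, axisb=0, axisc=0)
    return np.concatenate([np.asarray(c0)[None, ...], cv], axis=0)


def qconj(a) -> np.ndarray:
    """Quaternion conjugate ``A* = a0 − i a⃗``."""
    a = _asq(a, 4)
    out = a.copy()
    out[1:] *= -1.0
    return out


def qnorm(a) -> float | np.ndarray:
    """Euclidean norm ``sqrt(a0² + a⃗·a⃗)``."""
    return np.sqrt(np.sum(_asq(a, 4) ** 2, axis=0))


def qinv(a, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Inverse ``A⁻¹ = A*/‖A‖²``; raises on (near-)zero norm."""
    a = _asq(a, 4)
    n2 = np.sum(a**2, axis=0)
    if np.any(n2 <= tol**2):
        raise SingularElementError("qinv: zero-norm quaternion has no inverse")
    return qconj(a) / n2


# ---------------------------------------------------------------------------
# dual quaternions
# ---------------------------------------------------------------------------


def dq(real, dual) -> np.ndarray:
    """Assemble a dual quaternion ``D0 + ε D1`` from two quaternions."""
    real, dual = _asq(real, 4), _asq(dual, 4)
    real, dual = np.broadcast_arrays(real, dual)
    return np.concatenate([real, dual], axis=0)


def dq_identity(n: int | None = None) -> np.ndarray:
    if n is None:
        out = np.zeros(8)
        out[0] = 1.0
        return out
    out = np.zeros((8, n))
    out[0] = 1.0
    return out


def dq_from_quat(q) -> np.ndarray:
    """Promote a quaternion to a dual quaternion with zero dual part."""
    q = _asq(q, 4)
    return np.concatenate([q, np.zeros_like(q)], axis=0)


def dq_real(d) -> np.ndarray:
    return _asq(d, 8)[:4]


def dq_dual(d) -> np.ndarray:
    return _asq(d, 8)[4:]


def dqmul(d, e) -> np.ndarray:
    """Dual-quaternion product ``F0 = D0E0``, ``F1 = D0E1 + D1E0`` (ε² terms dropped)."""
    d, e = _align(_asq(d, 8), _asq(e, 8))
    f0 = qmul(d[:4], e[:4])
    f1 = qmul(d[:4], e[4:]) + qmul(d[4:], e[:4])
    return np.concatenate([f0, f1], axis=0)


_CONJ_KINDS = ("quaternion", "dual", "mixed")


def dqconj(d, kind: str = "quaternion") -> np.ndarray:
    """One of the three dual-quaternion conjugates.

    - ``"quaternion"``: ``D* = D0* + ε D1*``   (line sandwiches)
    - ``"dual"``:       ``D̄ = D0 − ε D1``
    - ``"mixed"``:      ``D̄* = D0* − ε D1*``   (point sandwiches)
    """
    d = _asq(d, 8)
    if kind == "quaternion":
        return np.concatenate([qconj(d[:4]), qconj(d[4:])], axis=0)
    if kind == "dual":
        return np.concatenate([d[:4], -d[4:]], axis=0)
    if kind == "mixed":
        return np.concatenate([qconj(d[:4]), -qconj(d[4:])], axis=0)
    raise UsageError(f"unknown conjugate kind {kind!r}; expected one of {_CONJ_KINDS}")


def dqnorm(d) -> DualNumber:
    """Norm as a dual number ``‖D0‖ + ε·[D0*D1 + D1*D0]_scalar / (2‖D0‖)``.

    For a zero-norm real part the dual component is undefined and reported
    as ``nan`` (flagged, not raised): such elements simply have no inverse.
    """
    d = _asq(d, 8)
    n0 = qnorm(d[:4])
    cross = qmul(qconj(d[:4]), d[4:]) + qmul(qconj(d[4:]), d[:4])
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(n0 > 0, cross[0] / (2.0 * np.where(n0 > 0, n0, 1.0)), np.nan)
    if np.ndim(n0) == 0:
        return DualNumber(float(n0), float(a1))
    return DualNumber(n0, a1)


def dqinv(d, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Inverse ``A⁻¹ = A*/‖A‖²`` (dual-number division); needs ‖A0‖ > 0."""
    d = _asq(d, 8)
    n = dqnorm(d)
    if np.any(np.asarray(n.a0) <= tol):
        raise SingularElementError("dqinv: dual quaternion with zero-norm real part has no inverse")
    # 1/‖A‖² as a dual number: (a0 + ε a1)⁻² = a0⁻² − ε 2 a1 a0⁻³
    inv_sq_re = 1.0 / n.a0**2
    inv_sq_du = -2.0 * n.a1 / n.a0**3
    c = dqconj(d, "quaternion")
    real = c[:4] * inv_sq_re
    dual = c[4:] * inv_sq_re + c[:4] * inv_sq_du
    return np.concatenate([real, dual], axis=0)


def unit_residuals(d) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Residuals of the two unit constraints ``‖D0‖ = 1`` and ``[D0*D1 + D1*D0]_0 = 0``.

    Unit dual quaternions form a 6-dimensional manifold inside ℝ⁸: the two
    scalar constraints returned here cut the dimension from 8 to 6.
    """
    d = _asq(d, 8)
    r1 = qnorm(d[:4]) - 1.0
    r2 = (qmul(qconj(d[:4]), d[4:]) + qmul(qconj(d[4:]), d[:4]))[0]
    return r1, r2


def is_unit(d, tol: float = DEFAULT_TOL) -> bool | np.ndarray:
    r1, r2 = unit_residuals(d)
    return (np.abs(r1) <= tol) & (np.abs(r2) <= tol)
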