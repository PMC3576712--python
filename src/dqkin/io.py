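"""Configuration (JSON) and trajectory (CSV) readers and writers.

Serialization contracts:

- a dual quaternion is always an 8-element array ordered
  ``[q0, qx, qy, qz, q0', qx', qy', qz']`` (real then dual part);
- point trajectories are CSV with header ``t,x,y,z`` (+ optional
  ``vx,vy,vz``), lines are ``t,nx,ny,nz,mx,my,mz``; units cm and s;
- numeric CSV output uses 12 significant digits;
- JSON configs are schema-validated (pydantic) and unknown keys are
  rejected.

Angles in JSON configs are degrees (``angle_deg``) because that is how
experimentalists write them; the library converts to radians at the
boundary and uses radians everywhere internally.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import UsageError
from .rigid import (
    RotationSpec,
    ScrewSpec,
    TranslationSpec,
    make_rotation,
    make_screw,
    make_translation,
)
from .visuomotor import BodyGeometry

__all__ = [
    "RotationModel",
    "MotionModel",
    "GeometryModel",
    "ArmModel",
    "CLIKModel",
    "load_json",
    "parse_motion",
    "parse_geometry",
    "read_point_trajectory",
    "write_point_trajectory",
    "write_error_report",
    "write_joint_series",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"

Vec3 = tuple[float, float, float]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RotationModel(_Strict):
    axis: Vec3 = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0

    def to_spec(self) -> RotationSpec:
        return RotationSpec(np.asarray(self.axis, dtype=float), np.deg2rad(self.angle_deg))


class MotionModel(_Strict):
    """One rigid-motion operator: rotation, translation or screw."""

    type: Literal["rotation", "translation", "screw"]
    axis: Vec3
    angle_deg: float = 0.0
    distance: float = 0.0
    point: Vec3 = (0.0, 0.0, 0.0)


class GeometryModel(_Strict):
    """Eye-head-shoulder geometry block (angles deg, offsets cm, velocities rad/s)."""

    eye_in_head: RotationModel = Field(default_factory=RotationModel)
    head_on_shoulder: RotationModel = Field(default_factory=RotationModel)
    t_he: Vec3 = (0.0, 0.0, 0.0)
    t_sh: Vec3 = (0.0, 0.0, 0.0)
    omega_eh: Vec3 = (0.0, 0.0, 0.0)
    omega_hs: Vec3 = (0.0, 0.0, 0.0)
    r_eye: float = 1.0


class ArmModel(_Strict):
    a: float = 30.0
    b: float = 30.0
    c: float | None = None  # present → three-link


class CLIKModel(_Strict):
    k1: float = 1000.0
    dt_s: float = 1e-3
    integrator: Literal["euler_renorm", "exp_map"] = "euler_renorm"
    sv_cutoff: float = 1e-10
    w: list[float] | None = None
    seed: int | None = None


def load_json(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise UsageError(f"invalid JSON in {path}: {exc}") from exc


def parse_motion(data: dict) -> np.ndarray:
    """Build the operator dual quaternion from a motion JSON block."""
    try:
        m = MotionModel.model_validate(data)
    except ValidationError as exc:
        raise UsageError(f"invalid motion spec: {exc}") from exc
    axis = np.asarray(m.axis, dtype=float)
    angle = float(np.deg2rad(m.angle_deg))
    if m.type == "rotation":
        return make_rotation(RotationSpec(axis, angle))
    if m.type == "translation":
        return make_translation(TranslationSpec(axis, m.distance))
    return make_screw(ScrewSpec(axis, angle, np.asarray(m.point, dtype=float), m.distance))


def parse_geometry(data: dict) -> BodyGeometry:
    try:
        g = GeometryModel.model_validate(data)
    except ValidationError as exc:
        raise UsageError(f"invalid geometry config: {exc}") from exc
    return BodyGeometry(
        eye_in_head=g.eye_in_head.to_spec(),
        head_on_shoulder=g.head_on_shoulder.to_spec(),
        t_he=np.asarray(g.t_he, dtype=float),
        t_sh=np.asarray(g.t_sh, dtype=float),
        omega_eh=np.asarray(g.omega_eh, dtype=float),
        omega_hs=np.asarray(g.omega_hs, dtype=float),
        r_eye=g.r_eye,
    )


def read_point_trajectory(path) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Read a ``t,x,y,z[,vx,vy,vz]`` CSV; returns (t, pos 3×N, vel 3×N or None)."""
    df = pd.read_csv(path)
    required = ["t", "x", "y", "z"]
    if not all(c in df.columns for c in required):
        raise UsageError(f"trajectory CSV must have columns {required}, got {list(df.columns)}")
    t = df["t"].to_numpy(dtype=float)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float).T
    vel = None
    if all(c in df.columns for c in ("vx", "vy", "vz")):
        vel = df[["vx", "vy", "vz"]].to_numpy(dtype=float).T
    return t, pos, vel


def write_point_trajectory(path, t, pos, vel=None) -> None:
    data = {"t": np.asarray(t), "x": pos[0], "y": pos[1], "z": pos[2]}
    if vel is not None:
        data.update({"vx": vel[0], "vy": vel[1], "vz": vel[2]})
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_error_report(path, t, errors, ranks=None, direction_errors=None) -> None:
    data = {"t": np.asarray(t), "error_cm": np.asarray(errors)}
    if direction_errors is not None:
        data["direction_error_rad"] = np.asarray(direction_errors)
    if ranks is not None:
        data["rank"] = np.asarray(ranks)
    pd.DataFrame(data).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_joint_series(path, result) -> None:
    """Write an IKResult's joint quaternion series (shoulder/elbow[/wrist]) to CSV."""
    cols = {"t": result.t}
    for name, series in (("shoulder", result.r_ub), ("elbow", result.r_lu), ("wrist", result.r_hl)):
        if series is None:
            continue
        for i, comp in enumerate(("w", "x", "y", "z")):
            cols[f"{name}_q{comp}"] = series[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)
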