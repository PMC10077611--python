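"""File I/O: meshes (STL/PLY/OBJ via trimesh), rim curves (CSV/JSON),
landmark files (JSON) and long-format measurement tables (CSV).

All coordinates are in mm.  Output CSVs carry ``# key: value`` comment
headers (seed, config hash) and are readable with
``pandas.read_csv(..., comment='#')``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

from .exceptions import ValidationError
from .frame import LandmarkSet, build_app_frame
from .hip import HipModel, RimCurve, fit_head_sphere

__all__ = [
    "load_rim",
    "save_rim",
    "load_mesh_vertices",
    "load_hip_model",
    "write_table",
    "read_table",
    "config_hash",
]

_MESH_SUFFIXES = {".stl", ".ply", ".obj"}


def load_rim(path) -> RimCurve:
    """Read an ordered rim curve from CSV (header x,y,z) or a JSON array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"rim file not found: {path}")
    if path.suffix.lower() == ".json":
        pts = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        df = pd.read_csv(path, comment="#")
        cols = [c.strip().lower() for c in df.columns]
        if not {"x", "y", "z"}.issubset(cols):
            raise ValidationError(f"rim CSV {path} must have columns x,y,z, got {list(df.columns)}")
        df.columns = cols
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return RimCurve(pts)


def save_rim(rim: RimCurve, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rim.points.tolist()))
    else:
        pd.DataFrame(rim.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def load_mesh_vertices(path) -> np.ndarray:
    """Vertices (mm) of a surface mesh; STL, PLY and OBJ are accepted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValidationError(
            f"unsupported mesh format {path.suffix!r} (expected STL, PLY or OBJ)"
        )
    mesh = trimesh.load(str(path), force="mesh")
    verts = np.asarray(mesh.vertices, dtype=float)
    if verts.size == 0:
        raise ValidationError(f"mesh {path} has no vertices")
    return verts


def _orient_rim_ccw(rim: RimCurve, frame) -> RimCurve:
    """Re-order the rim counter-clockwise when viewed from superior (+z)."""
    q = rim.points - rim.centroid
    x, y = q @ frame.x_axis, q @ frame.y_axis
    signed_area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed_area < 0:
        return RimCurve(rim.points[::-1].copy())
    return rim


def load_hip_model(
    mesh_path,
    landmarks_path,
    rim_path,
    side: str,
    sex: str = "unknown",
    hip_id: Optional[str] = None,
    subject_id: Optional[str] = None,
) -> HipModel:
    """Assemble and validate a hip model from its three input files.

    The head sphere is fitted to the mesh vertices (the mesh is expected
    to be head-only or pre-selected head vertices); the rim is re-ordered
    counter-clockwise viewed from superior.  Invariant violations raise
    :class:`~hipmorph.exceptions.ValidationError` naming the rule.
    """
    landmarks = LandmarkSet.from_json(landmarks_path)
    frame = build_app_frame(landmarks)
    sphere = fit_head_sphere(load_mesh_vertices(mesh_path))
    rim = _orient_rim_ccw(load_rim(rim_path), frame)
    model = HipModel(
        hip_id=hip_id or Path(str(mesh_path)).stem,
        side=side,
        sex=sex,
        sphere=sphere,
        rim=rim,
        landmarks=landmarks,
        frame=frame,
        subject_id=subject_id,
        mesh_ref=str(mesh_path),
    )
    model.validate()
    return model


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: Optional[dict] = None) -> None:
    """Write a CSV with ``# key: value`` header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
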