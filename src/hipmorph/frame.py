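"""Anterior-pelvic-plane (APP) coordinate frame and pelvic tilt poses.

The pelvic coordinate system is anchored on the line through both femoral
head centers and on the anterior pelvic plane (the plane through both
anterior superior iliac spines and the midpoint of the pubic tubercles):

* ``x_axis`` — from the left to the right femoral head center (lateral,
  toward the subject's right);
* ``z_axis`` — perpendicular to the x-axis and contained in the APP,
  pointing superiorly;
* ``y_axis`` — ``z × x``, completing a right-handed triad and pointing
  anteriorly.

APP tilt is a rotation of the pelvis about the x-axis line through the
midpoint of the head centers, so both femoral heads are fixed points
(the femur keeps its default posture while the pelvis tilts).  Positive
tilt is anterior (forward): the superior pelvis tips toward +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateGeometryError, ValidationError

__all__ = [
    "LandmarkSet",
    "PelvisFrame",
    "TiltPose",
    "build_app_frame",
    "make_tilt_pose",
]

_LANDMARK_KEYS = (
    "asis_left",
    "asis_right",
    "pubic_mid",
    "head_center_left",
    "head_center_right",
)

#: minimum area (mm^2) of the ASIS/pubic triangle before the APP is
#: considered degenerate, and minimum head-center separation (mm).
_MIN_TRIANGLE_AREA = 1e-6
_MIN_AXIS_LENGTH = 1e-9


def _as_point(value, name: str) -> np.ndarray:
    p = np.asarray(value, dtype=float)
    if p.shape != (3,) or not np.all(np.isfinite(p)):
        raise ValidationError(f"landmark {name!r} must be a finite 3D point, got {value!r}")
    return p


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < _MIN_AXIS_LENGTH:
        raise DegenerateGeometryError(f"cannot normalize near-zero vector for {what}")
    return v / n


@dataclass(frozen=True)
class LandmarkSet:
    """Pelvic landmarks, all in mm.

    ``asis_left``/``asis_right`` are the anterior superior iliac spines,
    ``pubic_mid`` the midpoint of the pubic tubercles; together they span
    the APP.  The two femoral head centers anchor the x-axis.
    """

    asis_left: np.ndarray
    asis_right: np.ndarray
    pubic_mid: np.ndarray
    head_center_left: np.ndarray
    head_center_right: np.ndarray

    def __post_init__(self):
        for key in _LANDMARK_KEYS:
            object.__setattr__(self, key, _as_point(getattr(self, key), key))
        self.validate()

    def validate(self) -> None:
        area = 0.5 * np.linalg.norm(
            np.cross(self.asis_right - self.asis_left, self.pubic_mid - self.asis_left)
        )
        if area < _MIN_TRIANGLE_AREA:
            raise DegenerateGeometryError(
                "APP landmarks (ASIS left/right, pubic midpoint) are collinear; "
                "they do not define a plane"
            )
        if np.linalg.norm(self.head_center_right - self.head_center_left) < _MIN_AXIS_LENGTH:
            raise DegenerateGeometryError("femoral head centers coincide; x-axis undefined")

    # -- serialization ------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        missing = [k for k in _LANDMARK_KEYS if k not in d]
        if missing:
            raise ValidationError(f"landmark file missing keys: {missing}")
        return cls(**{k: d[k] for k in _LANDMARK_KEYS})

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist() for k in _LANDMARK_KEYS}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def transformed(self, rotation: np.ndarray, pivot=None, translation=None) -> "LandmarkSet":
        """Apply ``p -> R (p - pivot) + pivot + t`` to every landmark."""
        pivot = np.zeros(3) if pivot is None else np.asarray(pivot, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        R = np.asarray(rotation, float)
        return LandmarkSet(
            **{
                k: R @ (getattr(self, k) - pivot) + pivot + t
                for k in _LANDMARK_KEYS
            }
        )


@dataclass(frozen=True)
class PelvisFrame:
    """Orthonormal right-handed pelvic frame (axes are unit 3-vectors).

    ``app_normal`` is the unit normal of the APP signed to point
    anteriorly; ``z_axis`` lies in the APP by construction.  ``y_axis``
    coincides with ``app_normal`` only when the head-center line is
    parallel to the APP (true for idealized anatomy).
    """

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    app_normal: np.ndarray = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        for k in ("x_axis", "y_axis", "z_axis", "app_normal"):
            v = getattr(self, k)
            if v is not None:
                object.__setattr__(self, k, np.asarray(v, float))

    @property
    def rotation(self) -> np.ndarray:
        """Columns are the frame axes: maps frame coordinates to world."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    def to_frame_coords(self, points: np.ndarray, origin=None) -> np.ndarray:
        """Express world points in this frame (optionally about another origin)."""
        o = self.origin if origin is None else np.asarray(origin, float)
        return (np.atleast_2d(points) - o) @ self.rotation

    def validate(self, tol: float = 1e-9) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise ValidationError("frame axes are not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > max(tol, 1e-9):
            raise ValidationError("frame is not right-handed")


def build_app_frame(landmarks: LandmarkSet) -> PelvisFrame:
    """Construct the pelvic frame from landmarks.

    The x-axis runs from the left to the right head center.  The APP
    normal is signed anterior using the fact that the femoral heads lie
    posterior to the APP; the z-axis (``app_normal × x``) is signed
    superior, toward the ASIS side of the pubic midpoint.
    """
    lm = landmarks
    lm.validate()
    x = _unit(lm.head_center_right - lm.head_center_left, "x-axis")

    n = np.cross(lm.asis_right - lm.asis_left, lm.pubic_mid - lm.asis_left)
    n = _unit(n, "APP normal")
    head_mid = 0.5 * (lm.head_center_left + lm.head_center_right)
    # heads sit posterior to the APP: flip n to point away from them
    if np.dot(n, head_mid - lm.pubic_mid) > 0:
        n = -n

    zx = np.cross(n, x)
    if np.linalg.norm(zx) < _MIN_AXIS_LENGTH:
        raise DegenerateGeometryError("head-center line is perpendicular to the APP")
    z = _unit(zx, "z-axis")
    asis_mid = 0.5 * (lm.asis_left + lm.asis_right)
    if np.dot(z, asis_mid - lm.pubic_mid) < 0:
        z = -z
    y = np.cross(z, x)

    frame = PelvisFrame(origin=head_mid, x_axis=x, y_axis=y, z_axis=z, app_normal=n)
    frame.validate()
    return frame


@dataclass(frozen=True)
class TiltPose:
    """Rigid APP-tilt pose: rotation about the frame's x-axis line.

    Positive ``app_tilt_deg`` is anterior tilt (z tips toward +y); the
    pivot lies on the head-center line, so both femoral heads are fixed.
    """

    app_tilt_deg: float
    rotation: np.ndarray
    pivot: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float))
        object.__setattr__(self, "pivot", np.asarray(self.pivot, float))

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        P = np.asarray(points, float)
        return (P - self.pivot) @ self.rotation.T + self.pivot

    def transform_point(self, point) -> np.ndarray:
        return self.transform_points(np.atleast_2d(point))[0]


def make_tilt_pose(frame: PelvisFrame, angle_deg: float) -> TiltPose:
    """Rotation by ``angle_deg`` about the x-axis line through the frame origin.

    With the right-handed frame (x lateral-right, y anterior, z superior),
    anterior tilt by +phi maps z to ``z cos(phi) + y sin(phi)``, which is a
    rotation about +x by -phi in the right-hand-rule sense.
    """
    if not np.isfinite(angle_deg):
        raise ValidationError("tilt angle must be finite")
    frame.validate()
    R = Rotation.from_rotvec(np.deg2rad(-float(angle_deg)) * frame.x_axis).as_matrix()
    return TiltPose(app_tilt_deg=float(angle_deg), rotation=R, pivot=frame.origin)
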