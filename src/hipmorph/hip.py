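"""Single-hip representation: femoral-head sphere, acetabular rim curve,
landmarks and metadata, plus sphere fitting and rim resampling."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateGeometryError, ValidationError
from .frame import LandmarkSet, PelvisFrame, TiltPose, build_app_frame

__all__ = [
    "HeadSphere",
    "RimCurve",
    "HipModel",
    "AngleMeasurement",
    "fit_head_sphere",
    "resample_rim",
    "apply_pose",
]

#: rim points must lie within this fraction of the head radius of the
#: sphere surface (default validation tolerance)
DEFAULT_RIM_TOL = 0.02

MIN_RIM_POINTS = 12


@dataclass(frozen=True)
class HeadSphere:
    """Femoral-head sphere: center in mm, radius in mm (> 0).

    ``rms`` is the root-mean-square radial residual of the fit that
    produced the sphere (0 for exactly constructed spheres).
    """

    center: np.ndarray
    radius: float
    rms: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValidationError(f"sphere radius must be positive and finite, got {self.radius}")

    def radial_error(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of each point from the sphere surface (mm)."""
        d = np.linalg.norm(np.atleast_2d(points) - self.center, axis=1)
        return d - self.radius


def fit_head_sphere(points) -> HeadSphere:
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic (linear) fit followed by geometric refinement minimizing
    sum(|p - c| - r)^2 with ``scipy.optimize.least_squares``.
    Deterministic for a fixed input.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("sphere fit expects an (n, 3) point array")
    if P.shape[0] < 4:
        raise DegenerateGeometryError(f"sphere fit needs >= 4 points, got {P.shape[0]}")

    # algebraic fit: |p|^2 = 2 c.p + (r^2 - |c|^2)
    A = np.column_stack([2.0 * P, np.ones(len(P))])
    b = np.einsum("ij,ij->i", P, P)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] < 1e-9 * sv[0]:
        raise DegenerateGeometryError(
            "sphere fit is degenerate (points are coplanar or otherwise "
            f"rank-deficient; singular values {sv})"
        )
    c0 = sol[:3]
    r0sq = sol[3] + c0 @ c0
    if r0sq <= 0:
        raise DegenerateGeometryError("algebraic sphere fit produced non-positive radius")
    r0 = float(np.sqrt(r0sq))

    def residual(x):
        return np.linalg.norm(P - x[:3], axis=1) - x[3]

    fit = least_squares(residual, x0=np.append(c0, r0), method="lm")
    c, r = fit.x[:3], float(fit.x[3])
    if not (np.isfinite(r) and r > 0):
        raise DegenerateGeometryError("geometric sphere refinement diverged")
    rms = float(np.sqrt(np.mean(residual(fit.x) ** 2)))
    return HeadSphere(center=c, radius=r, rms=rms)


@dataclass(frozen=True)
class RimCurve:
    """Closed, ordered acetabular rim polyline (points in mm).

    The curve is always treated as closed (last point connects back to
    the first; the first point is not repeated).
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self):
        P = np.asarray(self.points, dtype=float)
        if P.ndim != 2 or P.shape[1] != 3:
            raise ValidationError("rim must be an (n, 3) point array")
        if P.shape[0] < MIN_RIM_POINTS:
            raise ValidationError(
                f"rim needs >= {MIN_RIM_POINTS} points, got {P.shape[0]}"
            )
        object.__setattr__(self, "points", P)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def arc_length(self) -> float:
        """Total length of the closed polyline."""
        P = self.points
        seg = np.diff(np.vstack([P, P[:1]]), axis=0)
        return float(np.linalg.norm(seg, axis=1).sum())

    def best_fit_plane_normal(self) -> np.ndarray:
        """Unit normal of the least-squares plane through the rim points."""
        Q = self.points - self.centroid
        _, _, vt = np.linalg.svd(Q, full_matrices=False)
        return vt[2]

    def transformed(self, rotation: np.ndarray, pivot=None, translation=None) -> "RimCurve":
        pivot = np.zeros(3) if pivot is None else np.asarray(pivot, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        R = np.asarray(rotation, float)
        return RimCurve((self.points - pivot) @ R.T + pivot + t)


def resample_rim(rim: RimCurve, n: int) -> RimCurve:
    """Arc-length-uniform resampling of the closed rim to ``n`` points.

    Total arc length is preserved to well under 0.1% for densely sampled
    input curves; the first output point coincides with the first input
    point.
    """
    if n < MIN_RIM_POINTS:
        raise ValidationError(f"resampling needs n >= {MIN_RIM_POINTS}, got {n}")
    P = np.vstack([rim.points, rim.points[:1]])  # close the loop
    seg = np.linalg.norm(np.diff(P, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise DegenerateGeometryError("rim has zero length")
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.column_stack([np.interp(target, s, P[:, k]) for k in range(3)])
    return RimCurve(out)


@dataclass(frozen=True)
class AngleMeasurement:
    """Measurements of one hip at one APP tilt angle."""

    app_tilt_deg: float
    lcea_deg: float
    acea_deg: float
    coverage: float

    def __post_init__(self):
        if not (np.isfinite(self.lcea_deg) and np.isfinite(self.acea_deg)):
            raise ValidationError("angles must be finite")
        if not (-1e-9 <= self.coverage <= 1 + 1e-9):
            raise ValidationError(f"coverage must be in [0, 1], got {self.coverage}")


@dataclass(frozen=True)
class HipModel:
    """One hip: head sphere, ordered rim curve, landmarks and labels.

    ``frame`` is the neutral pelvic frame built from the landmarks at
    construction time.  It is the world (femur) reference and is kept
    fixed under tilt poses: the femur holds its default posture (its
    mechanical axis parallel to the neutral z-axis) while the pelvis —
    rim and landmarks — rotates.
    """

    hip_id: str
    side: str
    sex: str
    sphere: HeadSphere
    rim: RimCurve
    landmarks: LandmarkSet
    frame: PelvisFrame = None
    subject_id: Optional[str] = None
    mesh_ref: Optional[str] = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValidationError(f"sex must be male/female/unknown, got {self.sex!r}")
        if self.frame is None:
            object.__setattr__(self, "frame", build_app_frame(self.landmarks))

    @property
    def head_center(self) -> np.ndarray:
        return self.sphere.center

    def validate(self, tol_rim: float = DEFAULT_RIM_TOL) -> None:
        """Check rim-on-sphere and side-consistency invariants."""
        err = np.abs(self.sphere.radial_error(self.rim.points)) / self.sphere.radius
        bad = np.flatnonzero(err > tol_rim)
        if bad.size:
            worst = int(bad[np.argmax(err[bad])])
            raise ValidationError(
                f"rim point(s) {bad.tolist()} lie farther than {tol_rim:.1%} of the "
                f"head radius from the sphere surface (worst: index {worst}, "
                f"{err[worst]:.1%})"
            )
        own_center = getattr(self.landmarks, f"head_center_{self.side}")
        if np.linalg.norm(self.sphere.center - own_center) >= self.sphere.radius:
            raise ValidationError(
                f"side mismatch: fitted head center is not near the "
                f"{self.side} head-center landmark"
            )


def apply_pose(model: HipModel, pose: TiltPose) -> HipModel:
    """Rigidly rotate the pelvis (rim + landmarks) by a tilt pose.

    The head sphere and the neutral reference frame are unchanged: the
    head centers lie on the rotation axis and the femur stays in its
    default posture.  Side and sex labels are preserved.
    """
    return replace(
        model,
        rim=model.rim.transformed(pose.rotation, pivot=pose.pivot),
        landmarks=model.landmarks.transformed(pose.rotation, pivot=pose.pivot),
        frame=model.frame,
    )
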