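"""Morphometry of one hip: lateral and anterior center-edge angles and
horizontal-plane acetabular coverage, at any APP tilt, plus the tilt sweep.

Conventions
-----------
All measurements are expressed in the hip's *neutral* (world/femur)
frame, which is fixed while the pelvis tilts:

* LCEA — in the coronal cutting plane (normal = neutral y) through the
  most laterally protruding rim point ``e``: the signed angle between
  the vertical (neutral z) and the in-plane component of the vector from
  the head center ``c`` to ``e``.  Positive when ``e`` is lateral to the
  vertical through ``c``; edges medial to it give negative (dysplastic)
  angles.
* ACEA — same construction in the false-profile cutting plane, which
  contains the vertical and the direction ``u`` obtained by rotating the
  lateral axis 65 degrees toward anterior; ``e`` is the rim point most
  protruding along ``u``.
* Coverage — area of the horizontal projection of the superior-hemisphere
  surface points lying inside the acetabular cup, divided by the area of
  the projected superior hemisphere (pi r^2).  "Inside the cup" is the
  rim-bounded spherical region containing the cup pole.

Laterality is handled by the sign ``s`` (+1 right, -1 left) applied to
the lateral axis, so left and right hips are measured symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import UndefinedAngleError, ValidationError
from .frame import make_tilt_pose
from .hip import AngleMeasurement, HipModel, apply_pose, resample_rim

__all__ = [
    "MeasurementConfig",
    "TiltSweepResult",
    "lateral_rim_point",
    "anterolateral_rim_point",
    "measure_lcea",
    "measure_acea",
    "compute_coverage",
    "tilt_sweep",
]

DEFAULT_TILT_GRID = tuple(range(-30, 31, 5))


@dataclass(frozen=True)
class MeasurementConfig:
    """Tunable measurement parameters.

    ``tilt_grid`` — APP tilt angles in degrees (default -30..+30 step 5);
    ``false_profile_deg`` — rotation of the lateral axis toward anterior
    for the ACEA view (default 65);
    ``physiologic_range`` — the assumed normal span of APP tilt;
    ``rim_sampling_n`` — arc-length-uniform rim resampling used for the
    extremal-point searches;
    ``area_samples`` — grid resolution (points per axis across the head
    diameter) for the coverage integration.
    """

    tilt_grid: Sequence[float] = DEFAULT_TILT_GRID
    false_profile_deg: float = 65.0
    physiologic_range: tuple = (-10.0, 5.0)
    rim_sampling_n: int = 3600
    area_samples: int = 400

    def __post_init__(self):
        grid = tuple(float(a) for a in self.tilt_grid)
        if len(grid) == 0 or np.any(np.diff(grid) <= 0):
            raise ValidationError("tilt_grid must be non-empty and strictly increasing")
        if not (0.0 < self.false_profile_deg < 90.0):
            raise ValidationError("false_profile_deg must be in (0, 90)")
        if self.rim_sampling_n < 360:
            raise ValidationError("rim_sampling_n must be >= 360")
        object.__setattr__(self, "tilt_grid", grid)


def _laterality_sign(model: HipModel) -> float:
    return 1.0 if model.side == "right" else -1.0


def _extremal_rim_point(model: HipModel, direction: np.ndarray, n: int) -> np.ndarray:
    """Rim point maximizing ``p . direction``; ties broken superiorly."""
    P = resample_rim(model.rim, n).points
    score = P @ direction
    best = score.max()
    tied = np.flatnonzero(score >= best - 1e-9)
    if tied.size > 1:
        z = P[tied] @ model.frame.z_axis
        return P[tied[np.argmax(z)]]
    return P[tied[0]]


def lateral_rim_point(model: HipModel, config: MeasurementConfig = MeasurementConfig()) -> np.ndarray:
    """Most laterally protruding rim point (max of ``s * x`` over the rim)."""
    u = _laterality_sign(model) * model.frame.x_axis
    return _extremal_rim_point(model, u, config.rim_sampling_n)


def anterolateral_rim_point(
    model: HipModel, config: MeasurementConfig = MeasurementConfig()
) -> np.ndarray:
    """Most anterolaterally protruding rim point for the false-profile view."""
    s = _laterality_sign(model)
    fp = np.deg2rad(config.false_profile_deg)
    u = s * np.cos(fp) * model.frame.x_axis + np.sin(fp) * model.frame.y_axis
    return _extremal_rim_point(model, u, config.rim_sampling_n)


def _in_plane_angle(model: HipModel, edge: np.ndarray, in_plane_lateral: np.ndarray) -> float:
    """Signed angle (deg) from the vertical to c->edge within the cutting
    plane spanned by ``in_plane_lateral`` and the neutral z-axis."""
    rel = edge - model.head_center
    lat = float(rel @ in_plane_lateral)
    vert = float(rel @ model.frame.z_axis)
    if np.hypot(lat, vert) < 1e-9 * model.sphere.radius:
        raise UndefinedAngleError(
            "edge point projects onto the head center in the cutting plane"
        )
    return float(np.degrees(np.arctan2(lat, vert)))


def measure_lcea(model: HipModel, config: MeasurementConfig = MeasurementConfig()) -> float:
    """Lateral center-edge angle (degrees) in the current pose."""
    s = _laterality_sign(model)
    e = lateral_rim_point(model, config)
    return _in_plane_angle(model, e, s * model.frame.x_axis)


def measure_acea(model: HipModel, config: MeasurementConfig = MeasurementConfig()) -> float:
    """Anterior center-edge angle (degrees) in the current pose."""
    s = _laterality_sign(model)
    fp = np.deg2rad(config.false_profile_deg)
    u = s * np.cos(fp) * model.frame.x_axis + np.sin(fp) * model.frame.y_axis
    e = anterolateral_rim_point(model, config)
    return _in_plane_angle(model, e, u)


def _rim_colatitude_interp(model: HipModel, n: int):
    """Rim expressed as colatitude(azimuth) about the cup axis.

    The cup axis points from the head center toward the rim centroid
    (the cup pole side); azimuth is measured about it from an arbitrary
    in-plane reference.  Returns ``(axis, b1, b2, az_sorted, colat_sorted)``
    in neutral-frame coordinates.
    """
    frame, c = model.frame, model.head_center
    Q = frame.to_frame_coords(resample_rim(model.rim, n).points, origin=c)
    centroid = Q.mean(axis=0)
    norm = np.linalg.norm(centroid)
    if norm < 1e-9:
        raise ValidationError("rim centroid coincides with the head center; cup pole undefined")
    axis = centroid / norm
    # in-plane basis perpendicular to the cup axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    b1 = ref - (ref @ axis) * axis
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(axis, b1)
    d = Q / np.linalg.norm(Q, axis=1, keepdims=True)
    colat = np.arccos(np.clip(d @ axis, -1.0, 1.0))
    az = np.arctan2(d @ b2, d @ b1)
    order = np.argsort(az)
    return axis, b1, b2, az[order], colat[order]


def compute_coverage(model: HipModel, config: MeasurementConfig = MeasurementConfig()) -> float:
    """Horizontal-plane acetabular coverage fraction in [0, 1].

    Deterministic dense sampling: a regular grid over the projected
    superior-hemisphere disk; a grid point is covered when the superior
    sphere point above it lies inside the rim-bounded cup region.  Both
    numerator and denominator are counted on the same grid so the disk
    discretization cancels.
    """
    r = model.sphere.radius
    axis, b1, b2, az_r, colat_r = _rim_colatitude_interp(model, config.rim_sampling_n)

    m = config.area_samples
    ticks = (np.arange(m) + 0.5) / m * 2.0 - 1.0  # cell centers in (-1, 1)
    X, Y = np.meshgrid(ticks, ticks)
    rho2 = X**2 + Y**2
    disk = rho2 < 1.0
    Xd, Yd = X[disk], Y[disk]
    Z = np.sqrt(1.0 - (Xd**2 + Yd**2))
    d = np.column_stack([Xd, Yd, Z])  # unit directions, neutral-frame coords

    colat = np.arccos(np.clip(d @ axis, -1.0, 1.0))
    az = np.arctan2(d @ b2, d @ b1)
    # periodic linear interpolation of the rim colatitude
    az_ext = np.concatenate([az_r - 2 * np.pi, az_r, az_r + 2 * np.pi])
    colat_ext = np.concatenate([colat_r, colat_r, colat_r])
    rim_colat = np.interp(az, az_ext, colat_ext)
    inside = colat <= rim_colat
    return float(inside.sum() / disk.sum())


@dataclass(frozen=True)
class TiltSweepResult:
    """Per-angle LCEA/ACEA/coverage measurements for one hip."""

    hip_id: str
    side: str
    sex: str
    records: tuple = field(default_factory=tuple)
    subject_id: str = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hip_id": self.hip_id,
                "subject_id": self.subject_id if self.subject_id is not None else self.hip_id,
                "side": self.side,
                "sex": self.sex,
                "app_tilt_deg": [rec.app_tilt_deg for rec in self.records],
                "lcea_deg": [rec.lcea_deg for rec in self.records],
                "acea_deg": [rec.acea_deg for rec in self.records],
                "coverage": [rec.coverage for rec in self.records],
            }
        )


def tilt_sweep(model: HipModel, config: MeasurementConfig = MeasurementConfig()) -> TiltSweepResult:
    """Measure LCEA, ACEA and coverage at every angle of the tilt grid.

    The model must be in the neutral pose; each grid angle is an absolute
    tilt applied to the neutral model.
    """
    records = []
    for angle in config.tilt_grid:
        posed = apply_pose(model, make_tilt_pose(model.frame, angle))
        try:
            records.append(
                AngleMeasurement(
                    app_tilt_deg=float(angle),
                    lcea_deg=measure_lcea(posed, config),
                    acea_deg=measure_acea(posed, config),
                    coverage=compute_coverage(posed, config),
                )
            )
        except Exception as exc:
            raise type(exc)(f"at APP tilt {angle:+g} deg: {exc}") from exc
    return TiltSweepResult(
        hip_id=model.hip_id,
        side=model.side,
        sex=model.sex,
        records=tuple(records),
        subject_id=model.subject_id,
    )
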