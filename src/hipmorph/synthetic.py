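"""Parametric synthetic hips and bilateral cohorts with known ground truth.

The generator emulates the structure of a bilateral CT cohort of normal
adult hips: spherical femoral heads with a closed acetabular rim whose
colatitude about the cup axis is a two-harmonic function of azimuth,

    theta(psi) = theta0 + A1*cos(psi - psi1) + A2*cos(2*(psi - psi2)) + noise,

where azimuth ``psi`` is measured from lateral toward anterior.  The
default first harmonic (phase -90 deg: deepest coverage posterior,
shallowest anterior, as in real acetabula) tips the effective cup axis
posteriorly, so horizontal-plane coverage peaks at a positive
(anterior) APP tilt; the default second harmonic (phase 45 deg) shifts
the most-lateral rim point anteriorly without moving the effective cup
axis, so LCEA also peaks at a positive tilt.  The two roles cannot be
filled by a single harmonic: the lateral-point shift and the cup-axis
shift of a first harmonic both scale with A1*sin(psi1) and cancel
exactly.  Male rims have a larger mean colatitude than female rims
(default margin 3 deg), which produces male > female in all three
measures.

For axisymmetric, noiseless, untilted cups the ground truth is closed
form: LCEA = ACEA = theta0 and coverage = sin^2(theta0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

import pandas as pd

from .exceptions import ValidationError
from .frame import LandmarkSet
from .hip import HeadSphere, HipModel, RimCurve
from .measure import MeasurementConfig, tilt_sweep

__all__ = [
    "SyntheticHipParams",
    "SexDistribution",
    "CohortSpec",
    "canonical_landmarks",
    "generate_hip",
    "generate_cohort",
    "target_peak_angles",
]

#: landmark template (mm) for the canonical synthetic pelvis: head
#: centers on the x-axis, APP (ASIS pair + pubic midpoint) anterior to
#: and parallel to the head-center line.
_HEAD_HALF_SPAN = 90.0
_ASIS = np.array([120.0, 30.0, 70.0])
_PUBIC = np.array([0.0, 30.0, -70.0])


def canonical_landmarks() -> LandmarkSet:
    """Landmarks whose frame is the identity: x lateral-right, y anterior,
    z superior, origin at the midpoint of the head centers."""
    return LandmarkSet(
        asis_left=_ASIS * np.array([-1, 1, 1]),
        asis_right=_ASIS,
        pubic_mid=_PUBIC,
        head_center_left=np.array([-_HEAD_HALF_SPAN, 0.0, 0.0]),
        head_center_right=np.array([_HEAD_HALF_SPAN, 0.0, 0.0]),
    )


@dataclass(frozen=True)
class SyntheticHipParams:
    """Generative parameters of one hip (angles in degrees, lengths mm)."""

    head_radius: float = 24.0
    rim_colatitude_deg: float = 40.0
    rim_mod_amp_deg: float = 12.0
    rim_mod_phase_deg: float = -90.0
    rim_mod2_amp_deg: float = 8.0
    rim_mod2_phase_deg: float = 45.0
    cup_tilt_deg: float = 0.0
    rim_noise_deg: float = 0.3
    n_rim_points: int = 360
    seed: int = 0

    @property
    def total_mod_amp_deg(self) -> float:
        return abs(self.rim_mod_amp_deg) + abs(self.rim_mod2_amp_deg)

    def __post_init__(self):
        if self.head_radius <= 0:
            raise ValidationError("head_radius must be positive")
        if self.rim_colatitude_deg - self.total_mod_amp_deg <= 0:
            raise ValidationError("rim colatitude minus modulation amplitude must stay > 0")
        if self.rim_colatitude_deg + self.total_mod_amp_deg >= 90:
            raise ValidationError("rim colatitude plus modulation amplitude must stay < 90")
        if self.rim_noise_deg < 0:
            raise ValidationError("rim_noise_deg must be >= 0")
        if self.n_rim_points < 12:
            raise ValidationError("n_rim_points must be >= 12")


def generate_hip(
    params: SyntheticHipParams,
    side: str = "right",
    sex: str = "unknown",
    hip_id: str = "synthetic",
    subject_id: Optional[str] = None,
) -> tuple[HipModel, dict]:
    """Generate one hip model plus its ground-truth record.

    The head sphere sits at the canonical head center of the requested
    side; rim azimuth runs from lateral toward anterior, identically for
    both sides (a left hip is the mirror image of the same parameters).
    Deterministic for a fixed ``params.seed``.
    """
    lm = canonical_landmarks()
    s = 1.0 if side == "right" else -1.0
    center = np.array([s * _HEAD_HALF_SPAN, 0.0, 0.0])
    r = params.head_radius

    rng = np.random.default_rng(params.seed)
    psi = np.linspace(0.0, 2 * np.pi, params.n_rim_points, endpoint=False)
    theta = np.deg2rad(
        params.rim_colatitude_deg
        + params.rim_mod_amp_deg * np.cos(psi - np.deg2rad(params.rim_mod_phase_deg))
        + params.rim_mod2_amp_deg * np.cos(2.0 * (psi - np.deg2rad(params.rim_mod2_phase_deg)))
        + params.rim_noise_deg * rng.standard_normal(params.n_rim_points)
    )
    # lateral-anterior-superior basis for this side
    e1, e2, e3 = np.array([s, 0, 0.0]), np.array([0, 1, 0.0]), np.array([0, 0, 1.0])
    pts = r * (
        np.sin(theta)[:, None] * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
        + np.cos(theta)[:, None] * e3
    )
    # rigid cup pre-tilt about the x-axis: positive tips the cup axis anteriorly
    R = Rotation.from_rotvec(np.deg2rad(-params.cup_tilt_deg) * np.array([1.0, 0, 0])).as_matrix()
    pts = pts @ R.T + center

    model = HipModel(
        hip_id=hip_id,
        side=side,
        sex=sex,
        sphere=HeadSphere(center=center, radius=r),
        rim=RimCurve(pts),
        landmarks=lm,
        subject_id=subject_id,
    )
    truth = {
        "hip_id": hip_id,
        "subject_id": subject_id or hip_id,
        "side": side,
        "sex": sex,
        "head_radius": r,
        "rim_colatitude_deg": params.rim_colatitude_deg,
        "rim_mod_amp_deg": params.rim_mod_amp_deg,
        "rim_mod_phase_deg": params.rim_mod_phase_deg,
        "rim_mod2_amp_deg": params.rim_mod2_amp_deg,
        "rim_mod2_phase_deg": params.rim_mod2_phase_deg,
        "cup_tilt_deg": params.cup_tilt_deg,
        "rim_noise_deg": params.rim_noise_deg,
        "seed": params.seed,
    }
    if params.total_mod_amp_deg == 0 and params.rim_noise_deg == 0 and params.cup_tilt_deg == 0:
        th = np.deg2rad(params.rim_colatitude_deg)
        truth["lcea_deg_closed_form"] = params.rim_colatitude_deg
        truth["acea_deg_closed_form"] = params.rim_colatitude_deg
        truth["coverage_closed_form"] = float(np.sin(th) ** 2)
    return model, truth


@dataclass(frozen=True)
class SexDistribution:
    """Per-sex parameter distribution (means and SDs across subjects)."""

    radius_mean: float = 24.0
    radius_sd: float = 1.0
    colatitude_mean: float = 40.0
    colatitude_sd: float = 2.5
    mod_amp_mean: float = 12.0
    mod_amp_sd: float = 1.0
    mod_phase_mean: float = -90.0
    mod_phase_sd: float = 5.0
    mod2_amp_mean: float = 8.0
    mod2_amp_sd: float = 0.8
    mod2_phase_mean: float = 45.0
    mod2_phase_sd: float = 4.0
    cup_tilt_mean: float = 0.0
    cup_tilt_sd: float = 2.0
    rim_noise_deg: float = 0.3

    def __post_init__(self):
        for name in ("radius_sd", "colatitude_sd", "mod_amp_sd", "mod_phase_sd",
                     "mod2_amp_sd", "mod2_phase_sd", "cup_tilt_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def mean_params(self, **overrides) -> SyntheticHipParams:
        kw = dict(
            head_radius=self.radius_mean,
            rim_colatitude_deg=self.colatitude_mean,
            rim_mod_amp_deg=self.mod_amp_mean,
            rim_mod_phase_deg=self.mod_phase_mean,
            rim_mod2_amp_deg=self.mod2_amp_mean,
            rim_mod2_phase_deg=self.mod2_phase_mean,
            cup_tilt_deg=self.cup_tilt_mean,
            rim_noise_deg=0.0,
        )
        kw.update(overrides)
        return SyntheticHipParams(**kw)


#: adult femoral heads are larger in men; male rims sit ~3 deg deeper,
#: female rims are slightly more asymmetric
DEFAULT_MALE = SexDistribution(radius_mean=25.5, colatitude_mean=42.0, mod_amp_mean=12.0, mod2_amp_mean=8.0)
DEFAULT_FEMALE = SexDistribution(radius_mean=22.5, colatitude_mean=39.0, mod_amp_mean=13.0, mod2_amp_mean=8.5)


@dataclass(frozen=True)
class CohortSpec:
    """Bilateral cohort specification (defaults emulate a 71-subject,
    38 men / 33 women normal-hip study: 142 hips, 76 male / 66 female)."""

    n_male_subjects: int = 38
    n_female_subjects: int = 33
    male: SexDistribution = field(default_factory=lambda: DEFAULT_MALE)
    female: SexDistribution = field(default_factory=lambda: DEFAULT_FEMALE)
    bilateral: bool = True
    #: SD of the independent left/right jitter added to the shared
    #: subject parameters (degrees, applied to colatitude and amplitude)
    bilateral_jitter_deg: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_male_subjects < 1 or self.n_female_subjects < 1:
            raise ValidationError("subject counts must be >= 1")
        if self.bilateral_jitter_deg < 0:
            raise ValidationError("bilateral_jitter_deg must be >= 0")

    @classmethod
    def default(cls, seed: int = 0, colatitude_margin_deg: float = 3.0) -> "CohortSpec":
        """Default cohort with a configurable male-female colatitude margin."""
        female = replace(DEFAULT_FEMALE, colatitude_mean=DEFAULT_MALE.colatitude_mean - colatitude_margin_deg)
        return cls(male=DEFAULT_MALE, female=female, seed=seed)


def _draw_subject(rng, dist: SexDistribution) -> dict:
    return {
        "head_radius": float(np.clip(rng.normal(dist.radius_mean, dist.radius_sd), 15.0, 35.0)),
        "colatitude": float(rng.normal(dist.colatitude_mean, dist.colatitude_sd)),
        "amp": float(np.clip(rng.normal(dist.mod_amp_mean, dist.mod_amp_sd), 0.0, 25.0)),
        "phase": float(rng.normal(dist.mod_phase_mean, dist.mod_phase_sd)),
        "amp2": float(np.clip(rng.normal(dist.mod2_amp_mean, dist.mod2_amp_sd), 0.0, 15.0)),
        "phase2": float(rng.normal(dist.mod2_phase_mean, dist.mod2_phase_sd)),
        "cup_tilt": float(np.clip(rng.normal(dist.cup_tilt_mean, dist.cup_tilt_sd), -25.0, 25.0)),
    }


def generate_cohort(spec: CohortSpec) -> tuple[list[HipModel], pd.DataFrame]:
    """Generate the cohort; returns hip models and the ground-truth table.

    Subjects share their drawn parameters across sides (plus small
    independent jitter), emulating bilateral correlation; fully
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    hips: list[HipModel] = []
    truths: list[dict] = []
    sides = ("right", "left") if spec.bilateral else ("right",)
    groups = [("male", spec.n_male_subjects, spec.male), ("female", spec.n_female_subjects, spec.female)]
    subject_no = 0
    for sex, n_subjects, dist in groups:
        for _ in range(n_subjects):
            subject_no += 1
            subject_id = f"S{subject_no:03d}"
            draw = _draw_subject(rng, dist)
            for side in sides:
                colat = draw["colatitude"] + rng.normal(0.0, spec.bilateral_jitter_deg)
                amp = draw["amp"] + rng.normal(0.0, 0.6 * spec.bilateral_jitter_deg)
                amp = float(np.clip(amp, 0.0, 25.0))
                total_amp = amp + draw["amp2"]
                colat = float(np.clip(colat, total_amp + 2.0, 88.0 - total_amp))
                params = SyntheticHipParams(
                    head_radius=draw["head_radius"],
                    rim_colatitude_deg=colat,
                    rim_mod_amp_deg=amp,
                    rim_mod_phase_deg=draw["phase"],
                    rim_mod2_amp_deg=draw["amp2"],
                    rim_mod2_phase_deg=draw["phase2"],
                    cup_tilt_deg=draw["cup_tilt"],
                    rim_noise_deg=dist.rim_noise_deg,
                    seed=int(rng.integers(2**31)),
                )
                model, truth = generate_hip(
                    params,
                    side=side,
                    sex=sex,
                    hip_id=f"{subject_id}_{side[0].upper()}",
                    subject_id=subject_id,
                )
                hips.append(model)
                truths.append(truth)
    return hips, pd.DataFrame(truths)


def target_peak_angles(spec: CohortSpec, config: MeasurementConfig = MeasurementConfig()) -> dict:
    """Tilt angles at which the generator's mean geometry peaks.

    Sweeps the noiseless mean-parameter male and female hips, averages
    the curves weighted by hip counts, and returns the argmax grid angle
    per measure.  This is the cohort-level peak the generator targets.
    """
    weights = {"male": spec.n_male_subjects, "female": spec.n_female_subjects}
    curves = {}
    for sex, dist in (("male", spec.male), ("female", spec.female)):
        model, _ = generate_hip(dist.mean_params(), side="right", sex=sex, hip_id=f"mean_{sex}")
        curves[sex] = tilt_sweep(model, config).to_frame().set_index("app_tilt_deg")
    total = weights["male"] + weights["female"]
    out = {}
    for col, name in (("lcea_deg", "lcea"), ("acea_deg", "acea"), ("coverage", "coverage")):
        mean_curve = (
            weights["male"] * curves["male"][col] + weights["female"] * curves["female"][col]
        ) / total
        out[name] = float(mean_curve.idxmax())
    return out
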