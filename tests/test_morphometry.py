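"""Center-edge angles and coverage against closed forms and brute-force
oracles, plus symmetry/invariance properties."""

import numpy as np
import pytest

from hipmorph.frame import LandmarkSet, make_tilt_pose
from hipmorph.hip import HeadSphere, HipModel, RimCurve, apply_pose
from hipmorph.measure import (
    MeasurementConfig,
    anterolateral_rim_point,
    compute_coverage,
    lateral_rim_point,
    measure_acea,
    measure_lcea,
    tilt_sweep,
)
from hipmorph.synthetic import SyntheticHipParams, generate_hip

import oracles
from conftest import make_axisymmetric_hip, random_rotation

GRID = tuple(range(-30, 31, 5))


def tilted(model, phi):
    return apply_pose(model, make_tilt_pose(model.frame, phi))


class TestExtremalPoints:
    def test_axisymmetric_lateral_point_faces_lateral(self):
        model, _ = make_axisymmetric_hip(30.0)
        e = lateral_rim_point(model) - model.head_center
        r, th = model.sphere.radius, np.deg2rad(30)
        np.testing.assert_allclose(e, [r * np.sin(th), 0, r * np.cos(th)], atol=1e-3)

    def test_lateral_point_matches_brute_force_under_tilt(self, default_hip):
        model, _ = default_hip
        cfg = MeasurementConfig()
        from hipmorph.hip import resample_rim

        for phi in (-20.0, 0.0, 20.0):
            posed = tilted(model, phi)
            e = lateral_rim_point(posed, cfg)
            resampled = resample_rim(posed.rim, cfg.rim_sampling_n).points
            # exact argmax over the search set, and within chord sag of
            # the raw rim's exhaustive maximum
            assert e[0] >= resampled[:, 0].max() - 1e-12
            assert e[0] >= posed.rim.points[:, 0].max() - 2e-3 * model.sphere.radius

    def test_mirrored_left_hip_gives_mirror_point(self):
        right, _ = make_axisymmetric_hip(30.0, side="right")
        left, _ = make_axisymmetric_hip(30.0, side="left")
        er = lateral_rim_point(right) - right.head_center
        el = lateral_rim_point(left) - left.head_center
        np.testing.assert_allclose(el, er * np.array([-1, 1, 1]), atol=1e-9)

    def test_anterolateral_point_at_false_profile_azimuth(self):
        model, _ = make_axisymmetric_hip(30.0)
        e = anterolateral_rim_point(model) - model.head_center
        r, th, fp = model.sphere.radius, np.deg2rad(30), np.deg2rad(65)
        expected = [r * np.sin(th) * np.cos(fp), r * np.sin(th) * np.sin(fp), r * np.cos(th)]
        np.testing.assert_allclose(e, expected, atol=1e-3)

    def test_small_false_profile_angle_approaches_lateral_point(self, default_hip):
        model, _ = default_hip
        cfg = MeasurementConfig(false_profile_deg=0.1)
        np.testing.assert_allclose(
            anterolateral_rim_point(model, cfg), lateral_rim_point(model), atol=0.1
        )


class TestLCEA:
    def test_neutral_equals_colatitude(self):
        model, _ = make_axisymmetric_hip(30.0)
        assert abs(measure_lcea(model) - 30.0) < 1e-6

    @pytest.mark.parametrize("theta", [22.0, 30.0, 41.5])
    def test_closed_form_under_tilt(self, theta):
        model, _ = make_axisymmetric_hip(theta, n_rim=1440)
        for phi in GRID:
            got = measure_lcea(tilted(model, phi))
            assert abs(got - oracles.lcea_closed_form(theta, phi)) < 0.1

    def test_matches_brute_force_on_modulated_rim(self):
        # dense rim so the oracle's exhaustive scan sees the same spatial
        # resolution as the implementation's arc-length resampling
        model, _ = generate_hip(
            SyntheticHipParams(seed=42, rim_noise_deg=0.0, n_rim_points=3600)
        )
        for phi in GRID:
            got = measure_lcea(tilted(model, phi))
            want = oracles.brute_lcea(model.rim.points, model.head_center, 1.0, phi)
            assert abs(got - want) < 0.02

    def test_symmetric_in_tilt_for_axisymmetric_cup(self):
        model, _ = make_axisymmetric_hip(30.0)
        for phi in (5, 10, 20, 30):
            assert abs(measure_lcea(tilted(model, phi)) - measure_lcea(tilted(model, -phi))) < 0.05

    def test_zero_when_edge_on_vertical(self):
        """Tilting an axisymmetric cup laterally by exactly its rim
        colatitude puts the lateral edge on the vertical: LCEA = 0."""
        r, th = 24.0, np.deg2rad(30)
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        axis_pts = r * np.column_stack(
            [np.sin(th) * np.cos(t), np.sin(th) * np.sin(t), np.cos(th) * np.ones_like(t)]
        )
        # rotate about y by -30 deg: the psi=0 rim point moves to the pole
        a = -th
        Ry = np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])
        from hipmorph.synthetic import canonical_landmarks, _HEAD_HALF_SPAN

        c = np.array([_HEAD_HALF_SPAN, 0, 0])
        model = HipModel(
            hip_id="edgecase", side="right", sex="unknown",
            sphere=HeadSphere(c, r), rim=RimCurve(axis_pts @ Ry.T + c),
            landmarks=canonical_landmarks(),
        )
        assert abs(measure_lcea(model)) < 0.5


class TestACEA:
    def test_equals_lcea_for_axisymmetric_cup_at_neutral(self):
        for theta in (25.0, 30.0, 45.0):
            model, _ = make_axisymmetric_hip(theta)
            assert abs(measure_acea(model) - measure_lcea(model)) < 0.1

    def test_strictly_increasing_and_matches_brute_force(self):
        model, _ = make_axisymmetric_hip(30.0, n_rim=1440)
        vals = []
        for phi in GRID:
            got = measure_acea(tilted(model, phi))
            want = oracles.brute_acea(model.rim.points, model.head_center, 1.0, phi)
            assert abs(got - want) < 0.1
            assert abs(got - oracles.acea_closed_form(30.0, phi)) < 0.1
            vals.append(got)
        assert np.all(np.diff(vals) > 0)

    def test_positive_anterior_tilt_increases_acea(self):
        model, _ = make_axisymmetric_hip(30.0)
        assert measure_acea(tilted(model, 5.0)) > measure_acea(model)


class TestCoverage:
    @pytest.mark.parametrize("theta", [25.0, 35.0, 45.0])
    def test_polar_cap_closed_form(self, theta):
        model, _ = make_axisymmetric_hip(theta)
        expected = np.sin(np.deg2rad(theta)) ** 2
        assert abs(compute_coverage(model) - expected) < 0.005

    def test_resolution_refinement_stable(self):
        model, _ = generate_hip(SyntheticHipParams(seed=3))
        c1 = compute_coverage(model, MeasurementConfig(area_samples=400))
        c2 = compute_coverage(model, MeasurementConfig(area_samples=800))
        assert abs(c1 - c2) < 0.005

    def test_full_superior_hemisphere(self):
        model, _ = make_axisymmetric_hip(89.5)
        assert compute_coverage(model) > 0.98

    def test_small_polar_cap_vanishes(self):
        model, _ = make_axisymmetric_hip(2.0)
        assert compute_coverage(model) < 0.01

    def test_monte_carlo_oracle_on_modulated_tilted_hip(self, rng):
        model, _ = generate_hip(SyntheticHipParams(seed=11, rim_noise_deg=0.0))
        for phi in (-15.0, 10.0):
            posed = tilted(model, phi)
            got = compute_coverage(posed)
            want = oracles.mc_coverage(
                posed.rim.points, posed.head_center, posed.sphere.radius, rng
            )
            assert abs(got - want) < 0.01


class TestInvariances:
    @staticmethod
    def mirrored(model):
        M = np.diag([-1.0, 1.0, 1.0])
        lm = model.landmarks
        mirrored_lm = LandmarkSet(
            asis_left=M @ lm.asis_right,
            asis_right=M @ lm.asis_left,
            pubic_mid=M @ lm.pubic_mid,
            head_center_left=M @ lm.head_center_right,
            head_center_right=M @ lm.head_center_left,
        )
        return HipModel(
            hip_id=model.hip_id + "_mirror",
            side="left" if model.side == "right" else "right",
            sex=model.sex,
            sphere=HeadSphere(M @ model.sphere.center, model.sphere.radius),
            rim=RimCurve(model.rim.points @ M.T),
            landmarks=mirrored_lm,
        )

    def test_mirror_laterality_invariance(self, default_hip):
        model, _ = default_hip
        twin = self.mirrored(model)
        for phi in (-10.0, 0.0, 15.0):
            a, b = tilted(model, phi), tilted(twin, phi)
            assert abs(measure_lcea(a) - measure_lcea(b)) < 1e-6
            assert abs(measure_acea(a) - measure_acea(b)) < 1e-6
            assert abs(compute_coverage(a) - compute_coverage(b)) < 1e-6

    def test_rigid_motion_invariance(self, default_hip, rng):
        model, _ = default_hip
        R = random_rotation(rng)
        t = rng.normal(0, 50, 3)
        moved = HipModel(
            hip_id="moved", side=model.side, sex=model.sex,
            sphere=HeadSphere(R @ model.sphere.center + t, model.sphere.radius),
            rim=RimCurve(model.rim.points @ R.T + t),
            landmarks=model.landmarks.transformed(R, translation=t),
        )
        for phi in (0.0, 12.5):
            a, b = tilted(model, phi), tilted(moved, phi)
            assert abs(measure_lcea(a) - measure_lcea(b)) < 1e-6
            assert abs(measure_acea(a) - measure_acea(b)) < 1e-6
            assert abs(compute_coverage(a) - compute_coverage(b)) < 1e-6


class TestTiltSweep:
    def test_neutral_record_matches_direct_measurement(self, default_hip):
        model, _ = default_hip
        cfg = MeasurementConfig(tilt_grid=(0.0,))
        sweep = tilt_sweep(model, cfg)
        assert len(sweep.records) == 1
        rec = sweep.records[0]
        assert abs(rec.lcea_deg - measure_lcea(model, cfg)) < 1e-12
        assert abs(rec.acea_deg - measure_acea(model, cfg)) < 1e-12
        assert abs(rec.coverage - compute_coverage(model, cfg)) < 1e-12

    def test_grid_shape_and_order(self, default_hip):
        model, _ = default_hip
        sweep = tilt_sweep(model)
        angles = [rec.app_tilt_deg for rec in sweep.records]
        assert angles == list(map(float, GRID))

    def test_default_generator_peaks(self, default_hip):
        """Generator defaults: LCEA argmax positive, ACEA strictly
        increasing across the grid."""
        model, _ = default_hip
        df = tilt_sweep(model).to_frame().set_index("app_tilt_deg")
        assert df["lcea_deg"].idxmax() > 0
        assert np.all(np.diff(df["acea_deg"].to_numpy()) > 0)
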