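import numpy as np
import pytest

from hipmorph.synthetic import SyntheticHipParams, generate_hip


@pytest.fixture
def rng():
    return np.random.default_rng(20230405)


def make_axisymmetric_hip(theta_deg, radius=24.0, side="right", n_rim=720):
    """Noiseless axisymmetric cup: closed-form LCEA=ACEA=theta,
    coverage=sin^2(theta) at neutral."""
    params = SyntheticHipParams(
        head_radius=radius,
        rim_colatitude_deg=theta_deg,
        rim_mod_amp_deg=0.0,
        rim_mod2_amp_deg=0.0,
        cup_tilt_deg=0.0,
        rim_noise_deg=0.0,
        n_rim_points=n_rim,
    )
    model, truth = generate_hip(params, side=side)
    return model, truth


@pytest.fixture
def axisym_hip():
    return make_axisymmetric_hip


@pytest.fixture
def default_hip():
    """One hip drawn from the generator's default (modulated) family."""
    model, truth = generate_hip(SyntheticHipParams(seed=42), side="right", sex="male")
    return model, truth


def random_landmarks(rng):
    """Random non-degenerate landmark set in general position."""
    from hipmorph.frame import LandmarkSet

    while True:
        try:
            asis_l = rng.normal([-120, 30, 70], 8)
            asis_r = rng.normal([120, 30, 70], 8)
            pubic = rng.normal([0, 30, -70], 8)
            hc_l = rng.normal([-90, 0, 0], 5)
            hc_r = rng.normal([90, 0, 0], 5)
            return LandmarkSet(asis_l, asis_r, pubic, hc_l, hc_r)
        except Exception:
            continue


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
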