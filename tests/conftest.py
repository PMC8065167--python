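import numpy as np
import pytest

from onhmorph.synthetic import SyntheticEyeParams, simulate_eye

HIGH_MYOPIA_SECTORS = {
    "mrw": {"T": 155.6, "ST": 170.9, "SN": 192.0, "N": 211.1, "IN": 217.0, "IT": 178.5},
    "rnfl": {"T": 58.8, "ST": 85.2, "SN": 71.4, "N": 57.7, "IN": 70.3, "IT": 89.2},
    "pct": {"T": 95.0, "ST": 114.1, "SN": 128.7, "N": 128.6, "IN": 100.0, "IT": 82.7},
}


def make_eye_params(**overrides) -> SyntheticEyeParams:
    """A high-myopia-like synthetic eye, noiseless unless overridden."""
    defaults = dict(
        true_tilt_deg=3.4,
        true_rotation_deg=36.7,
        true_ovality=0.85,
        bmo_semimajor_um=860.0,
        mrw_profile=HIGH_MYOPIA_SECTORS["mrw"],
        rnfl_profile_um=HIGH_MYOPIA_SECTORS["rnfl"],
        choroid_profile_um=HIGH_MYOPIA_SECTORS["pct"],
        fobmo_deg=-7.0,
        point_noise_sd_um=0.0,
        boundary_noise_sd_um=0.0,
    )
    defaults.update(overrides)
    return SyntheticEyeParams(**defaults)


@pytest.fixture
def noiseless_eye():
    """(scans, profile, truth) of a noiseless high-myopia-like eye."""
    return simulate_eye(make_eye_params(), seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
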