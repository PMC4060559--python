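import pytest

from vergefmri import (
    CalibrationModel,
    VergenceResponseSpec,
    generate_block_timeline,
    generate_vergence_trial,
)


@pytest.fixture(scope="session")
def study_timeline():
    """The study's block design: 20 s phases, 3.5 cycles, 3-5 s illuminations."""
    return generate_block_timeline(20.0, 3.5, 3.0, 5.0, seed=42)


@pytest.fixture(scope="session")
def identity_like_calibration():
    """Simple symmetric calibration: 10 deg/V per eye, zero offsets."""
    return CalibrationModel(10.0, 0.0, 10.0, 0.0)


@pytest.fixture()
def clean_step_trial(identity_like_calibration):
    """Noise-free 4 deg convergence step with a 20 deg/s peak velocity."""
    spec = VergenceResponseSpec(peak_velocity=20.0, noise_sd_deg=0.0)
    return generate_vergence_trial(spec, identity_like_calibration, seed=7)
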