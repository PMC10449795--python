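import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from redpupil.simulate import (
    FAR_RED,
    MELANIN_DARK_BROWN,
    PLRProtocol,
    PupilDynamicsParams,
    SpectralEyeParams,
    default_glare_spots,
    render_eye_frame,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture
def dark_eye() -> SpectralEyeParams:
    """Noise- and glare-free dark-brown iris eye."""
    return SpectralEyeParams(melanin_load=MELANIN_DARK_BROWN, noise_sd=0.0)


@pytest.fixture
def study_eye() -> SpectralEyeParams:
    """A realistic capture: dark iris, sensor noise, LED glare near the pupil."""
    base = SpectralEyeParams(melanin_load=2.0, noise_sd=3.0)
    return SpectralEyeParams(
        melanin_load=2.0, noise_sd=3.0, glare_spots=default_glare_spots(base, 60.0)
    )


@pytest.fixture
def study_frame(study_eye) -> np.ndarray:
    return render_eye_frame(study_eye, 60.0, FAR_RED, seed=11)


@pytest.fixture
def default_dynamics() -> PupilDynamicsParams:
    return PupilDynamicsParams(baseline_diameter_px=60.0, constriction_amplitude=0.3)


@pytest.fixture
def short_protocol() -> PLRProtocol:
    """A 1 s recording at 60 Hz for fast video-level tests."""
    return PLRProtocol(pre_stimulus_s=0.3, stimulus_s=0.2, post_stimulus_s=0.5)
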