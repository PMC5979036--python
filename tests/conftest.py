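import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dscmri import AcquisitionParams, default_spec, generate_phantom

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acq_default() -> AcquisitionParams:
    """The emulated rodent DSC acquisition (TE 5 ms, TR 1 s, 850 frames)."""
    return AcquisitionParams(
        te=0.005, tr=1.0, n_frames=850, baseline_frames=200, bolus_start_frame=240
    )


@pytest.fixture(scope="session")
def acq_short() -> AcquisitionParams:
    """A short acquisition for cheap synthetic unit tests."""
    return AcquisitionParams(
        te=0.005, tr=1.0, n_frames=160, baseline_frames=30, bolus_start_frame=40
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noise-free two-class phantom shared across tests."""
    spec = default_spec(shape=(6, 6, 2), noise_sd_frac=0.0, seed=1)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Small 1%-noise two-class phantom shared across tests."""
    spec = default_spec(shape=(6, 6, 2), noise_sd_frac=0.01, seed=7)
    return generate_phantom(spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
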