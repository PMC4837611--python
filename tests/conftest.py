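import numpy as np
import pytest

from gaitmatch import GaitParams, generate_trial
from gaitmatch.synthetic_gait import noise_sd_for_snr_db


@pytest.fixture(scope="session")
def default_params() -> GaitParams:
    return GaitParams()


@pytest.fixture(scope="session")
def noiseless_trial():
    """One clean symmetric episode of 10 heel strikes."""
    return generate_trial(GaitParams(n_steps=10, step_cv=0.0, asymmetry=0.0, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def jittered_trial():
    """Mildly variable, slightly asymmetric, low-noise episode."""
    return generate_trial(GaitParams(n_steps=11, step_cv=0.02, asymmetry=0.02, noise_sd=0.05, seed=7))


@pytest.fixture(scope="session")
def snr10_noise_sd() -> float:
    """Peak-relative noise SD giving 10 dB RMS SNR on the lower-back waveform."""
    return noise_sd_for_snr_db(GaitParams(), 10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
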