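import numpy as np
import pytest

from fafnet.config import EEGGroundTruth, ParadigmConfig, VocalGroundTruth


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def tiny_paradigm():
    """Four vocalizations, eight channels: enough trials for every stage."""
    return ParadigmConfig(n_vocalizations=4, eeg_channels=8)


@pytest.fixture
def quiet_eeg_truth():
    """Deterministic EEG content: no noise, no theta, no artifacts."""
    return EEGGroundTruth(noise_sd_uv=0.0, theta_amp_uv=0.0)


@pytest.fixture
def clean_vocal_truth():
    return VocalGroundTruth(response_magnitude_cents=15.0,
                            response_latency_ms=100.0, jitter_sd_cents=0.0)
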