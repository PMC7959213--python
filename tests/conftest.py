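import numpy as np
import pytest

from cbloop.preprocess import EEGSegment
from cbloop.stimulus import make_templates
from cbloop.synth import AttentionTrace, EEGGenParams


@pytest.fixture(scope="session")
def templates_5s():
    return make_templates(f0=1.875, fs=256.0, duration=5.0)


@pytest.fixture(scope="session")
def templates_6s():
    return make_templates(f0=1.875, fs=256.0, duration=6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_gen():
    """Small, quick generator config for unit tests."""
    return EEGGenParams(
        n_channels=8,
        fs_raw=512.0,
        attended_gain=1.0,
        unattended_gain=0.3,
        noise_sd=0.5,
        noise_spectrum="white",
        mixing_seed=7,
        noise_seed=11,
    )


@pytest.fixture
def face_trace():
    return AttentionTrace(duration=5.0, initial_state="face")


def random_segment(rng, n_samples=512, n_channels=4, fs=256.0):
    return EEGSegment(data=rng.standard_normal((n_samples, n_channels)), fs=fs)


@pytest.fixture
def segment_factory(rng):
    def _make(n_samples=512, n_channels=4, fs=256.0):
        return random_segment(rng, n_samples, n_channels, fs)

    return _make
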