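import numpy as np
import pytest

from stochvoc import (
    VocoderConfig,
    Waveform,
    make_chirp,
    make_noise,
    make_word_like,
)


@pytest.fixture(scope="session")
def demo_chirp() -> Waveform:
    """The broadband demo chirp: 20 Hz-12 kHz, peak 0.1, 20-ms ramps, 44.1 kHz."""
    return make_chirp(20.0, 12000.0, 1.0, 0.1, 0.02, 44100.0)


@pytest.fixture(scope="session")
def word() -> Waveform:
    return make_word_like(0.5, 22050.0, seed=0)


@pytest.fixture(scope="session")
def pink_noise_44k(demo_chirp) -> Waveform:
    return make_noise("pink", demo_chirp.duration, demo_chirp.fs, rms=demo_chirp.rms(), seed=99)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def constant_wave(value: float, n: int = 100_000, fs: float = 22050.0) -> Waveform:
    return Waveform(np.full(n, value), fs)


@pytest.fixture()
def default_config() -> VocoderConfig:
    return VocoderConfig(n_samplers=300, seed=1)
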