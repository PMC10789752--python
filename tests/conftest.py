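import numpy as np
import pytest

from preictal import SpectrogramConfig, Spectrogram, SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def spec_cfg():
    return SpectrogramConfig()


@pytest.fixture(scope="session")
def tiny_recording():
    """Small two-channel, two-seizure synthetic recording shared by the
    IO/segmentation tests."""
    cfg = SynthConfig(n_channels=2, n_seizures=2, seed=5, effect_size=3.0)
    rec, ann = generate_recording(cfg)
    return cfg, rec, ann


@pytest.fixture
def make_spec(rng):
    """Factory for random spectrograms with the standard 21 x 60 axes."""

    def _make(n_channels=3, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return Spectrogram(
            values=r.random((n_channels, 21, 60)) + 0.5,
            frame_times=np.arange(21) * 0.5,
            bin_freqs=np.arange(60.0),
        )

    return _make
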