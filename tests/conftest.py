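import numpy as np
import pytest

from qeegpod.features import FeatureConfig
from qeegpod.profiles import make_band_profile
from qeegpod.recording import STANDARD_CHANNELS, EEGRecording
from qeegpod.simulate import synthesize_recording


@pytest.fixture(scope="session")
def config():
    return FeatureConfig()


@pytest.fixture(scope="session")
def slow_heavy_profile():
    """Delta-dominant profile typical of a sedated, slowed EEG."""
    fr = np.array([80.29, 9.85, 6.42, 3.447])
    return make_band_profile(fr / fr.sum())


@pytest.fixture(scope="session")
def mixed_profile():
    """More broadband profile typical of lighter sedation."""
    fr = np.array([58.49, 11.64, 17.27, 12.61])
    return make_band_profile(fr / fr.sum())


@pytest.fixture(scope="session")
def short_recording(slow_heavy_profile):
    return synthesize_recording(slow_heavy_profile, duration_s=40.0, fs=256.0, seed=7)


def sinusoid_recording(freq_hz, amplitude_uv=1.0, duration_s=60.0, fs=256.0, n_channels=2):
    t = np.arange(int(duration_s * fs)) / fs
    x = amplitude_uv * np.sin(2 * np.pi * freq_hz * t)
    return EEGRecording(
        samples=np.tile(x, (n_channels, 1)),
        fs=fs,
        channel_labels=tuple(STANDARD_CHANNELS[:n_channels]),
    )
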