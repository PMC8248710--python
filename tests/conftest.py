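"""Shared fixtures: small synthetic recordings and their features."""

import numpy as np
import pytest

from lungsed import (
    Recording,
    SynthConfig,
    extract_features,
    generate_recording,
)


@pytest.fixture(scope="session")
def synth_config():
    return SynthConfig(seed=123)


@pytest.fixture(scope="session")
def synth_recording(synth_config):
    rec, labels = generate_recording(synth_config)
    return rec, labels


@pytest.fixture(scope="session")
def synth_features(synth_recording):
    rec, labels = synth_recording
    features, spectrogram = extract_features(rec)
    return features, spectrogram, labels


@pytest.fixture()
def tone_recording():
    """Pure 250-Hz tone at the center of spectrogram bin 16."""
    t = np.arange(60000) / 4000.0
    return Recording(samples=0.5 * np.sin(2 * np.pi * 250.0 * t), id="tone250")
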