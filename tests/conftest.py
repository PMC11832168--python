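import numpy as np
import pytest

from slentrain import montage, streamgen


@pytest.fixture(scope="session")
def lexicon_a():
    return streamgen.build_lexicon("phoneme", "A")


@pytest.fixture(scope="session")
def lexicon_b():
    return streamgen.build_lexicon("phoneme", "B")


@pytest.fixture(scope="session")
def positions_16():
    return montage.make_montage(16)


@pytest.fixture(scope="session")
def positions_128():
    return montage.make_montage(128)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def pure_tone_epochs(n_epochs, n_channels, freq_hz=4.0, n_samples=1875,
                     srate=250.0, phase=0.0, amplitude=1.0):
    """Identical-phase sinusoidal epochs (helper shared across test modules)."""
    t = np.arange(n_samples) / srate
    sig = amplitude * np.sin(2 * np.pi * freq_hz * t + phase)
    return np.tile(sig, (n_epochs, n_channels, 1))
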