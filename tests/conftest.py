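import numpy as np
import pytest

from hdqeeg.io import CANONICAL_CHANNELS, EEGRecording, apply_average_reference


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def short_recording():
    """60-s white-noise recording at 250 Hz, average-referenced."""
    gen = np.random.default_rng(7)
    rec = EEGRecording(gen.normal(0.0, 20.0, (19, 250 * 60)), 250.0, CANONICAL_CHANNELS)
    return apply_average_reference(rec)


@pytest.fixture(scope="session")
def short_spectrum_set(short_recording):
    from hdqeeg.spectra import compute_spectrum_set

    return compute_spectrum_set(short_recording)
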