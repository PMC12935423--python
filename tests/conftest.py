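import numpy as np
import pytest

from bradyssa.types import GyroRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def tone_recording():
    """4-second 5 Hz tone riding on a slow drift, fs = 250 Hz."""
    fs = 250.0
    t = np.arange(int(4 * fs)) / fs
    samples = 30.0 * np.sin(2 * np.pi * 5.0 * t) + 5.0 * t
    return GyroRecording(participant_id="EG01", cohort="EG", state="OFF",
                         phase=4, fs=fs, samples=samples)
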