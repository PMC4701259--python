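import numpy as np
import pytest

from emgspike.data import EMGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_noise_recording(
    rng: np.random.Generator,
    n_channels: int = 2,
    duration_s: float = 0.5,
    rate: float = 400.0,
    amplitude: float = 5e-5,
) -> EMGRecording:
    """Plain white-noise recording for extractor unit tests."""
    n = round(duration_s * rate)
    data = rng.standard_normal((n_channels, n)) * amplitude
    return EMGRecording(rate, data, np.zeros(n, dtype=np.int64))


@pytest.fixture
def noise_recording(rng):
    return make_noise_recording(rng)
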