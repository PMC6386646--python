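import numpy as np
import pytest

from har import (
    CANONICAL_CHANNELS,
    SensorStream,
    default_models,
    default_protocol,
    simulate_activity_stream,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_stream(data, rate_hz=50.0, channels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1] and data.shape[0] <= 6:
        data = data.T
    n, c = data.shape
    if channels is None:
        channels = CANONICAL_CHANNELS[:c]
    period = int(round(1000.0 / rate_hz))
    ts = np.arange(n, dtype=np.int64) * period
    return SensorStream(ts, data, channels, rate_hz)


@pytest.fixture
def six_channel_stream(rng):
    """2 s of noisy 6-channel data at 50 Hz."""
    return make_stream(rng.standard_normal((100, 6)), rate_hz=50.0)


@pytest.fixture
def desk_session():
    """One clean labeled synthetic session (5.5 min at 20 Hz)."""
    return simulate_activity_stream(default_protocol("desk"), default_models(), seed=7)
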