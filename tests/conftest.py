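import numpy as np
import pytest

from swrkit.io import ContinuousTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(samples, rate=1000.0, t0=0.0, units=""):
    return ContinuousTrace(samples=np.asarray(samples, dtype=float),
                           rate=rate, t0=t0, units=units)


def sinusoid(freq_hz, duration_s, rate_hz, amplitude=1.0):
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    return make_trace(amplitude * np.sin(2 * np.pi * freq_hz * t),
                      rate=rate_hz)
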