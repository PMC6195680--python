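import numpy as np
import pytest

from mousecam.containers import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_timeseries(values, rate=100.0, units=""):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    times = np.arange(values.shape[1]) / rate
    return TimeSeries(times=times, values=values, rate=rate, units=units)


@pytest.fixture
def ts_factory():
    return make_timeseries


def textured_image(rng, shape=(120, 160), smooth=2.0):
    """Random smooth texture with full 8-bit dynamic range."""
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(rng.uniform(0, 1, shape), smooth)
    img = (img - img.min()) / (img.max() - img.min())
    return (img * 255).astype(np.uint8)
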