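import numpy as np
import pytest

from h2sindex.timeseries import GasTimeSeries

EPOCH = np.datetime64("2021-06-01T06:00:00", "ns")


def _make_series(readings, dt=10.0, start=EPOCH):
    readings = np.asarray(readings, dtype=float)
    step = np.timedelta64(int(round(dt * 1e9)), "ns")
    ts = start + np.arange(len(readings)) * step
    return GasTimeSeries(timestamps=ts, readings=readings, logging_interval=dt)


@pytest.fixture
def make_series():
    """Factory: a regular-grid series from a list of readings (default 10-s)."""
    return _make_series


@pytest.fixture
def single_spike_series(make_series):
    """One isolated 8.0-ppm sample in a long zero shift, 10-s logging."""
    r = np.zeros(1000)
    r[500] = 8.0
    return make_series(r)
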