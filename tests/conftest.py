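import numpy as np
import pytest

from cycleforecast.containers import HeartRateSeries

T0 = np.datetime64("2020-01-01T00:00:00", "ns")


def make_hr(values, start=T0, mask=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros(values.size, dtype=bool)
    return HeartRateSeries(start_time=start, values=values, missing_mask=mask)


def sinusoid_hr(duration_days, period_days, amplitude=5.0, baseline=70.0,
                start=T0):
    n = int(duration_days * 288)
    t = np.arange(n) / 288.0
    return make_hr(baseline + amplitude * np.cos(2 * np.pi * t / period_days),
                   start=start)


@pytest.fixture
def t0():
    return T0
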