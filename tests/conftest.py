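import numpy as np
import pytest

from gaitmon import AccelTrace, ScalarSeries, SubjectProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile():
    return SubjectProfile()


@pytest.fixture
def quiet_trace():
    """Constant gravity on z, zero elsewhere: a perfectly still foot."""
    n = 500
    return AccelTrace(100.0, 0.0, np.zeros(n), np.zeros(n), np.full(n, 9.80665))


def series(values, rate=100.0, t0=0.0):
    return ScalarSeries(rate, t0, np.asarray(values, dtype=float))
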