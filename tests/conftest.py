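import numpy as np
import pytest

from thermoclean import FilterConfig, LabelVector, TemperatureTrace


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def flat_trace():
    """10 readings of 36.8 °C at 1-minute intervals."""
    times = np.arange(10.0)
    return TemperatureTrace("flat", times, np.full(10, 36.8))


@pytest.fixture
def dip_trace():
    return TemperatureTrace("dip", [0, 1, 2, 3, 4], [36.8, 36.8, 33.0, 36.8, 36.8])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def labels_for(trace, flagged=()):
    arr = np.zeros(len(trace), dtype=np.int8)
    arr[list(flagged)] = 1
    return LabelVector(trace.case_id, arr)


@pytest.fixture
def make_labels():
    return labels_for
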