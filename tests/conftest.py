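import numpy as np
import pytest

from hrvcomplexity.sigio import EventSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rri(rng):
    """A plausible random RR-interval series (ms), 300 beats."""
    intervals = 900.0 + 40.0 * rng.standard_normal(300)
    return EventSeries.from_intervals(intervals, kind="RRi")


def make_rri(values):
    return EventSeries.from_intervals(np.asarray(values, dtype=float),
                                      kind="RRi")
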