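import numpy as np
import pytest
from hypothesis import settings

from hrvdvc import PhysioBounds, RRSeries

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def bounds() -> PhysioBounds:
    return PhysioBounds()


@pytest.fixture
def constant_series() -> RRSeries:
    return RRSeries.from_intervals([0.8] * 12)


def make_series(intervals, t0: float = 0.0, label=None) -> RRSeries:
    return RRSeries.from_intervals(intervals, t0=t0, label=label)


@pytest.fixture
def make_rr():
    return make_series
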