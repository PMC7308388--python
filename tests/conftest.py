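import numpy as np
import pytest

from numsense.stimulus_space import StimulusPoint


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mid_point():
    """A mid-range full-scale stimulus point used in several oracles."""
    return StimulusPoint(n=18, size=6.55e5, spacing=2.02e7)


@pytest.fixture
def small_point():
    """A point that renders fast on a small canvas."""
    return StimulusPoint(n=7, size=5000.0, spacing=3.0e5)
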