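import numpy as np
import pytest

from ncaperm import XYDataSet, load_worked_example

# Fig-1-style envelope: upper limits for u = 3 and lower limits for l = 5
UPPER_U3 = np.array([3, 4, 5, 6, 7, 8, 9, 9, 9], dtype=float)
LOWER_L5 = np.array([1, 1, 1, 1, 1, 2, 3, 4, 5], dtype=float)
X19 = np.arange(1, 10, dtype=float)


@pytest.fixture(scope="session")
def worked_example():
    """The printed 12-point worked example and its ten reshuffles."""
    return load_worked_example()


@pytest.fixture()
def upper_trace():
    """Points tracing the u = 3 upper limits, anchored at y = 1 so the
    observed scope spans the full [1,9] x [1,9] square."""
    return XYDataSet(np.r_[X19, X19], np.r_[UPPER_U3, np.ones(9)])


@pytest.fixture()
def lower_trace():
    """Points tracing the l = 5 lower limits, anchored at y = 9."""
    return XYDataSet(np.r_[X19, X19], np.r_[LOWER_L5, np.full(9, 9.0)])
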