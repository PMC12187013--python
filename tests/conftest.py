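import numpy as np
import pytest

from predimer import Trace


def make_trace(values, channel="R", cell_id="c1", dt=5.0):
    values = np.asarray(values, dtype=float)
    times = np.arange(values.size) * dt
    return Trace(cell_id=cell_id, channel=channel, times=times, values=values)


@pytest.fixture
def step_trace():
    """Trace rising from 0 to a plateau of 10 after frame 3 (dt = 5 min)."""
    return make_trace([0, 0, 0, 0, 2, 8, 10, 10])


@pytest.fixture
def flat_trace():
    return make_trace([1.0] * 8)
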