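import numpy as np
import pytest

from gazebias.task_engine import GazeTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(x, y=None, fs=600.0, valid=None):
    """Build a uniformly sampled trace from position arrays."""
    x = np.asarray(x, dtype=float)
    if y is None:
        y = np.zeros_like(x)
    t = np.arange(x.size) / fs
    return GazeTrace(t, x, y, valid, fs=fs)


@pytest.fixture
def make_trace_fn():
    return make_trace
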