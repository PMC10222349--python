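import numpy as np
import pytest

from tibrestore import SyntheticRunConfig, generate_run
from tibrestore.trace import TriaxialTrace


@pytest.fixture(scope="session")
def run600():
    """One mid-sized synthetic run shared by statistics-hungry tests."""
    cfg = SyntheticRunConfig(n_strides=600, seed=7)
    high, low, truth = generate_run(cfg)
    return cfg, high, low, truth


def make_trace(values_y, rate_hz=1125.0, range_g=16.0, x=None, z=None):
    """Build a trace from an axial series (x/z default to zero)."""
    values_y = np.asarray(values_y, float)
    n = values_y.size
    a = np.zeros((n, 3))
    a[:, 1] = values_y
    if x is not None:
        a[:, 0] = x
    if z is not None:
        a[:, 2] = z
    t = np.arange(n) / rate_hz
    return TriaxialTrace(t=t, a=a, rate_hz=rate_hz, range_g=range_g)


@pytest.fixture
def trace_factory():
    return make_trace
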