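import numpy as np
import pytest

from neuromapper import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def planar_points(rng):
    """Random 20-point planar configuration (for embedding recovery)."""
    return rng.standard_normal((20, 2))


def make_data(values, tr=1.0, labels=None):
    return DataMatrix(np.asarray(values, dtype=float), tr=tr, labels=labels)
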