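import numpy as np
import pytest

from hots.theory import AggregationParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hl1_params():
    """Cohesion energy and configurational area of the native cardiac-cell
    muscarinic-receptor fit (near-critical regime)."""
    return AggregationParams(dG_bulk=-1.24, A0=0.58)


@pytest.fixture
def cho_params():
    """Overexpression-series fit parameters (stronger cohesion, smaller A0)."""
    return AggregationParams(dG_bulk=-1.82, A0=0.08)
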