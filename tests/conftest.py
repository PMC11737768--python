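import numpy as np
import pytest

from hleird import HleirdParams, load_builtin


@pytest.fixture(scope="session")
def fibers_20mm():
    return load_builtin("carbon_fiber_20mm")


@pytest.fixture(scope="session")
def fibers_10mm():
    return load_builtin("carbon_fiber_10mm")


@pytest.fixture(scope="session")
def param_grid():
    """Small spread of parameter triples covering skinny and heavy shapes."""
    return [
        HleirdParams(1.0, 1.0, 1.0),
        HleirdParams(2.0, 2.0, 2.0),
        HleirdParams(0.5, 0.5, 2.0),
        HleirdParams(1.5, 0.7, 3.0),
        HleirdParams(3.0, 1.0, 0.8),
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
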