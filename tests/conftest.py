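import numpy as np
import pytest

from coffo import Bounds, Problem, make_sphere


@pytest.fixture
def sphere1d():
    return make_sphere(1, -1.0, 1.0)


@pytest.fixture
def sphere2d():
    return make_sphere(2, -5.0, 5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_bounds():
    return Bounds.box(-1.0, 1.0, 3)
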