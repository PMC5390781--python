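import numpy as np
import pytest
from hypothesis import settings

from nirmix import DEFAULT_GRID, SmoothingParams, build_library
from nirmix.synthetic import default_component_specs, make_component

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def components(grid):
    return [make_component(spec, grid) for spec in default_component_specs()]


@pytest.fixture(scope="session")
def library(grid, components):
    return build_library(components, grid)


@pytest.fixture
def params():
    return SmoothingParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160118)
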