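import numpy as np
import pytest
from hypothesis import settings

import tubeswarm as ts

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tube_a():
    """Symmetric fixture with Tube A's 29.05-degree opening angle."""
    return ts.make_tube_fixture(29.05, tube_id="A")


@pytest.fixture(scope="session")
def rectangle_tube():
    return ts.make_tube_fixture(0.0, tube_id="rect")


@pytest.fixture(scope="session")
def tube_a_polygons(tube_a):
    return ts.build_region_polygons(tube_a)


@pytest.fixture(scope="session")
def frame37():
    """Bundled 16-fish frame table (includes the known glitch row)."""
    return ts.datasets.load_tube_a_frame37()


@pytest.fixture(scope="session")
def tube_a_stats():
    return ts.datasets.load_tube_a_region_stats()


@pytest.fixture(scope="session")
def tube_summaries():
    return ts.datasets.load_tube_summaries()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
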