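import numpy as np
import pytest

from graphskipgram.graph import Graph, karate_fixture


@pytest.fixture(scope="session")
def karate() -> Graph:
    return karate_fixture()


@pytest.fixture
def triangle() -> Graph:
    return Graph.from_edges([("1", "2"), ("2", "3"), ("3", "1")])


@pytest.fixture
def path4() -> Graph:
    return Graph.from_edges([("1", "2"), ("2", "3"), ("3", "4")])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
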