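import pytest

from dscentrality import random_graph, toy_graph


@pytest.fixture
def path3():
    return toy_graph("path", 3)


@pytest.fixture
def triangle():
    return toy_graph("complete", 3)


@pytest.fixture
def k2():
    return toy_graph("complete", 2)


@pytest.fixture
def k4():
    return toy_graph("complete", 4)


@pytest.fixture
def star4():
    """Star with 4 leaves: center node 0 has degree 4."""
    return toy_graph("star", 4)


@pytest.fixture
def triangle_pendant():
    return toy_graph("triangle_pendant")


@pytest.fixture(scope="session")
def er50():
    return random_graph("er", 7, n=50, p=0.2)


@pytest.fixture(scope="session")
def ba200():
    """The default stand-in for the empirical benchmark networks."""
    return random_graph("ba", 1, n=200, m=3)
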