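import pytest

from evograph.graph_core import make_named_graph, sample_er_connected


@pytest.fixture(scope="session")
def star8():
    return make_named_graph("star", 8)


@pytest.fixture(scope="session")
def complete8():
    return make_named_graph("complete", 8)


@pytest.fixture(scope="session")
def cycle8():
    return make_named_graph("cycle", 8)


@pytest.fixture(scope="session")
def er_graphs():
    """A handful of small connected ER graphs for property-style checks."""
    return [sample_er_connected(7, 0.45, seed) for seed in range(6)]
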