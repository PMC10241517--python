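import numpy as np
import pytest

from netlearn.graphs import PARADIGMS, build_graph, transition_matrix


@pytest.fixture(scope="session")
def graphs():
    """One canonical graph per paradigm."""
    return {p: build_graph(p, rng_seed=10 + i) for i, p in enumerate(PARADIGMS)}


@pytest.fixture(scope="session")
def matrices(graphs):
    return {p: transition_matrix(g) for p, g in graphs.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
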