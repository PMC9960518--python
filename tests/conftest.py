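import numpy as np
import pytest

from ctclmap import SyntheticConfig, simulate_registry
from ctclmap.geography import AdjacencyGraph


@pytest.fixture(scope="session")
def small_registry():
    """An 8x8-tract synthetic registry with the default generating truth."""
    config = SyntheticConfig(grid_rows=8, grid_cols=8, seed=42)
    tracts, graph, counts, truth = simulate_registry(config)
    return config, tracts, graph, counts, truth


@pytest.fixture()
def pair_graph():
    return AdjacencyGraph.from_edges(["a", "b"], [("a", "b")])


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
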