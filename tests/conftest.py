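import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from seednet import TradeNetwork

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_net(edges: dict[tuple[str, str], float], focal=None,
             window_years=10) -> TradeNetwork:
    """Build a TradeNetwork directly from an edge -> tonnes/yr mapping."""
    g = nx.DiGraph()
    for (o, d), v in edges.items():
        g.add_edge(o, d, tonnes_per_year=v)
    return TradeNetwork(graph=g, focal=focal, window_years=window_years)


@pytest.fixture
def triangle_net():
    """3-node cycle A->B->C->A, one tonne/yr each."""
    return make_net({("A", "B"): 1.0, ("B", "C"): 1.0, ("C", "A"): 1.0})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
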