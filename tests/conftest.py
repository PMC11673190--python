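import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_families():
    """Five well-separated synthetic RT families with ground truth."""
    from retronet import SimulationConfig, simulate_rt_families

    cfg = SimulationConfig(
        n_groups=5, sizes=[16] * 5, within_rate=0.05, between_rate=0.8, seed=7
    )
    return simulate_rt_families(cfg)


@pytest.fixture
def bridge_triangles():
    """Two triangles joined by one bridge edge; known optimum partition."""
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]
    )
    return g
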