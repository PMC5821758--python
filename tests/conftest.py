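import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from cadnet.simulate import SimulationConfig, simulate_all

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A compact but fully featured study configuration."""
    return SimulationConfig(
        n_loci=12,
        genes_per_locus=4,
        n_networks=4,
        nodes_per_network=24,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim(small_config):
    """All synthetic inputs generated once for read-only tests."""
    return simulate_all(small_config)


@pytest.fixture()
def two_triangles_bridge() -> nx.Graph:
    """Two triangles {a,b,c} and {d,e,f} joined by the bridge (c, d)."""
    g = nx.Graph()
    g.add_edges_from(
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f"),
         ("c", "d")]
    )
    return g
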