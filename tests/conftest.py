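import networkx as nx
import pytest

from netpharm import (
    PPINetwork,
    SyntheticConfig,
    run_pipeline,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard benchmark bundle (default config, seed 42)."""
    return simulate_bundle(SyntheticConfig())


@pytest.fixture(scope="session")
def default_pipeline_result():
    """Full pipeline run on the standard synthetic bundle."""
    return run_pipeline({"simulate": {"seed": 42}})


def random_ppi(n: int, p: float, seed: int) -> PPINetwork:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return PPINetwork.from_edges(
        ((f"N{u:02d}", f"N{v:02d}") for u, v in g.edges()),
        extra_nodes=(f"N{u:02d}" for u in g.nodes()),
    )
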