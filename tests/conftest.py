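import networkx as nx
import pytest

from coopnet.geometry import PSModelParams
from coopnet.synthetic import ps_generate


@pytest.fixture(scope="session")
def ps_params_cold():
    """Low-temperature PS parameters: strong geometric signal."""
    return PSModelParams(temperature=0.1)


@pytest.fixture(scope="session")
def ps_params_study():
    """The study's embedding parameters (gamma 2.97, T 0.83, full circle)."""
    return PSModelParams()


@pytest.fixture(scope="session")
def small_ps_embedding(ps_params_study):
    """A 400-node PS network with ground-truth coordinates, shared across tests."""
    return ps_generate(ps_params_study, 400, seed=11)


@pytest.fixture()
def path_graph_abc():
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g
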