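import networkx as nx
import numpy as np
import pytest

from netpharm.model import AnnotatedNetwork, ROLE_OTHER
from netpharm.simulate import generate_study


def random_annotated_network(
    rng: np.random.Generator, n: int, p: float, scored: bool = False
) -> AnnotatedNetwork:
    """Erdős–Rényi graph wrapped as an AnnotatedNetwork with 'other' roles."""
    net = AnnotatedNetwork()
    nodes = [f"N{i:02d}" for i in range(n)]
    for node in nodes:
        net.add_node(node, ROLE_OTHER)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                score = float(rng.random()) if scored else None
                net.add_edge(nodes[i], nodes[j], kind="pp", score=score)
    return net


def path_network(*nodes) -> AnnotatedNetwork:
    net = AnnotatedNetwork()
    for n in nodes:
        net.add_node(n, ROLE_OTHER)
    for a, b in zip(nodes, nodes[1:]):
        net.add_edge(a, b, kind="pp")
    return net


def clique_graph(labels) -> nx.Graph:
    g = nx.Graph()
    labels = list(labels)
    g.add_nodes_from(labels)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            g.add_edge(labels[i], labels[j])
    return g


@pytest.fixture(scope="session")
def study():
    """One synthetic study at generator defaults, shared across tests."""
    return generate_study(seed=101)


@pytest.fixture(scope="session")
def study_paths(study, tmp_path_factory):
    return study.write(tmp_path_factory.mktemp("study"))
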