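import networkx as nx
import pytest

from ppdt import (
    InteractionNetwork,
    generate_annotation,
    generate_expression,
    generate_gene_sets,
    generate_network,
)


@pytest.fixture(scope="session")
def synthetic_study():
    """One default synthetic study: network, truth, gene sets, catalog, expression."""
    net, truth = generate_network(seed=1)
    genes_a, genes_b, targets_b = generate_gene_sets(truth, seed=2)
    catalog = generate_annotation(truth, seed=3)
    expr = generate_expression(truth, seed=4)
    return {
        "net": net,
        "truth": truth,
        "genes_a": genes_a,
        "genes_b": genes_b,
        "targets_b": targets_b,
        "catalog": catalog,
        "expr": expr,
    }


@pytest.fixture()
def bridged_cliques():
    """Two 5-cliques joined by a single bridge edge."""
    g = nx.Graph()
    left = [f"A{i}" for i in range(5)]
    right = [f"B{i}" for i in range(5)]
    for clique in (left, right):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(clique[i], clique[j])
    g.add_edge("A0", "B0")
    return InteractionNetwork(g), frozenset(left), frozenset(right)


@pytest.fixture()
def path_graph():
    g = nx.path_graph(["A", "B", "C", "D", "E"])
    return InteractionNetwork(g)
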