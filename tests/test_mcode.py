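"""MCODE: vertex weighting, complex prediction, scoring, planted-module recovery."""

import networkx as nx
import numpy as np
import pytest

from netpharm.errors import UsageError
from netpharm.mcode import (
    McodeParams,
    complex_score,
    find_complexes,
    score_vertices,
)
from netpharm.simulate import generate_ppi

from conftest import clique_graph
from _oracles import brute_mcode_weight


class TestVertexWeights:
    def test_isolated_edge_below_degree_cutoff(self):
        g = nx.Graph([("A", "B")])
        assert score_vertices(g) == {"A": 0.0, "B": 0.0}

    def test_four_clique_weight_is_three(self):
        g = clique_graph("ABCD")
        w = score_vertices(g)
        # closed neighbourhood = the 4-clique; highest core k=3, density 1
        assert all(v == pytest.approx(3.0) for v in w.values())

    def test_planted_clique_outweighs_background(self):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        clique = [f"C{i}" for i in range(6)]
        g.add_edges_from(clique_graph(clique).edges)
        background = [f"B{i}" for i in range(40)]
        for i in range(40):
            for j in range(i + 1, 40):
                if rng.random() < 0.05:
                    g.add_edge(background[i], background[j])
        g.add_edge("C0", "B0")  # attach the clique to the background
        w = score_vertices(g)
        assert min(w[c] for c in clique) > max(w[b] for b in background if b in w)

    @pytest.mark.parametrize("graph_seed", range(4))
    def test_matches_brute_force_weight_evaluation(self, graph_seed):
        rng = np.random.default_rng(graph_seed)
        n = 20
        nodes = [f"N{i:02d}" for i in range(n)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.25:
                    g.add_edge(nodes[i], nodes[j])
        w = score_vertices(g)
        edges = [tuple(sorted(e)) for e in g.edges]
        for v in nodes:
            assert w[v] == pytest.approx(brute_mcode_weight(nodes, edges, v), abs=1e-12)


class TestFindComplexes:
    def test_bridged_equal_cliques_merge_per_expansion_rule(self):
        # every vertex weighs 4.0, so the admission bar (3.2) is crossed via
        # the bridge and the two 5-cliques form one complex
        g = nx.Graph()
        g.add_edges_from(clique_graph([f"A{i}" for i in range(5)]).edges)
        g.add_edges_from(clique_graph([f"B{i}" for i in range(5)]).edges)
        g.add_edge("A0", "B0")
        mods = find_complexes(g)
        assert len(mods) == 1
        assert len(mods[0].members) == 10
        assert mods[0].score == pytest.approx(10 * 21 / 45)

    def test_bridged_unequal_cliques_stay_separate(self):
        # 6-clique weighs 5.0, 5-clique weighs 4.0 <= 0.8*5.0: bar not met
        g = nx.Graph()
        g.add_edges_from(clique_graph([f"A{i}" for i in range(6)]).edges)
        g.add_edges_from(clique_graph([f"B{i}" for i in range(5)]).edges)
        g.add_edge("A0", "B0")
        mods = find_complexes(g)
        assert [len(m.members) for m in mods] == [6, 5]
        assert [m.score for m in mods] == [pytest.approx(6.0), pytest.approx(5.0)]

    def test_edgeless_graph_yields_nothing(self):
        g = nx.Graph()
        g.add_nodes_from("ABC")
        assert find_complexes(g) == []

    def test_complexes_disjoint_and_ranked(self):
        edges, planted, _ = generate_ppi(seed=3)
        g = nx.Graph((e.protein_a, e.protein_b) for e in edges if e.score > 0.7)
        mods = find_complexes(g)
        seen = set()
        for m in mods:
            assert not (m.members & seen)
            seen |= m.members
            assert m.seed in m.members
            assert len(m.members) >= 2
            assert m.score <= len(m.members) + 1e-12
            assert m.score == pytest.approx(complex_score(g, m.members))
        assert [m.rank for m in mods] == list(range(1, len(mods) + 1))
        assert all(a.score >= b.score for a, b in zip(mods, mods[1:]))

    def test_deterministic_under_input_reordering(self):
        edges, _, _ = generate_ppi(n_nodes=120, seed=5)
        kept = [(e.protein_a, e.protein_b) for e in edges if e.score > 0.7]
        g1 = nx.Graph(kept)
        g2 = nx.Graph(list(reversed(kept)))
        m1, m2 = find_complexes(g1), find_complexes(g2)
        assert [(m.members, m.seed, m.score) for m in m1] == \
               [(m.members, m.seed, m.score) for m in m2]

    def test_haircut_removes_singly_connected_member(self):
        # triangle ABC plus P (itself in triangle PQR) hanging off A: with
        # max_depth 1 the complex grows to {A,B,C,P}; P is singly connected
        # inside it, so the haircut trims the complex back to the triangle
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C"),
                      ("A", "P"), ("P", "Q"), ("Q", "R"), ("P", "R")])
        with_haircut = find_complexes(g, params=McodeParams(haircut=True, max_depth=1))
        assert with_haircut[0].members == frozenset("ABC")
        without = find_complexes(g, params=McodeParams(haircut=False, max_depth=1))
        assert without[0].members == frozenset("ABCP")

    def test_planted_modules_recovered(self):
        edges, planted, _ = generate_ppi(seed=11)
        g = nx.Graph((e.protein_a, e.protein_b) for e in edges if e.score > 0.7)
        mods = find_complexes(g)
        for module in planted:
            best = max(
                len(module & m.members) / len(module | m.members) for m in mods
            )
            assert best >= 0.8


class TestComplexScore:
    def test_triangle_scores_three(self):
        assert complex_score(clique_graph("ABC"), "ABC") == pytest.approx(3.0)

    def test_four_cycle_score(self):
        g = nx.cycle_graph(4)
        assert complex_score(g, [0, 1, 2, 3]) == pytest.approx(8 / 3)

    @pytest.mark.parametrize("k", [2, 5, 9])
    def test_clique_scores_its_size(self, k):
        labels = [f"N{i}" for i in range(k)]
        assert complex_score(clique_graph(labels), labels) == pytest.approx(k)

    def test_members_outside_network_rejected(self):
        with pytest.raises(UsageError):
            complex_score(clique_graph("ABC"), ["A", "Q"])

    def test_singleton_rejected(self):
        with pytest.raises(UsageError):
            complex_score(clique_graph("ABC"), ["A"])


def test_params_validated():
    with pytest.raises(UsageError):
        McodeParams(degree_cutoff=0)
    with pytest.raises(UsageError):
        McodeParams(node_score_cutoff=1.0)
    with pytest.raises(UsageError):
        McodeParams(k_core=1)
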