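"""Construction of the bipartite, expansion and intersection networks."""

import numpy as np
import pytest

from netpharm.errors import UsageError
from netpharm.model import (
    AnnotatedNetwork,
    CompoundTargetRecord,
    InteractionEdge,
    ROLE_COMPOUND_TARGET,
    ROLE_DISEASE_TARGET,
    ROLE_OTHER,
    ROLE_SHARED_TARGET,
)
from netpharm.networks import (
    build_bipartite_network,
    expand_with_interactors,
    intersect_networks,
    summarize_network,
)

from _oracles import brute_expand


def _ct(pairs):
    return [CompoundTargetRecord(c, t) for c, t in pairs]


def _edges(triples):
    return [InteractionEdge(a, b, s) for a, b, s in triples]


class TestBipartite:
    def test_disjoint_targets_roles(self):
        net = build_bipartite_network(_ct([("c1", "T1"), ("c1", "T2"), ("c2", "T3")]))
        assert net.n_nodes() == 5
        assert net.role_counts() == {"compound": 2, "compound_target": 3}

    def test_shared_targets_flagged(self):
        net = build_bipartite_network(
            _ct([("c1", "T1"), ("c1", "T2")]), disease_targets=["T2", "T9"]
        )
        assert net.role("T2") == ROLE_SHARED_TARGET
        assert net.role("T1") == ROLE_COMPOUND_TARGET

    def test_role_counts_sum_to_node_total(self, study):
        net = build_bipartite_network(study.compound_targets, study.truth.disease_union)
        summary = summarize_network(net)
        assert sum(summary["role_counts"].values()) == summary["n_nodes"]
        assert summary["role_counts"]["compound"] == 32
        assert summary["n_edges"] == len(study.compound_targets)

    def test_record_order_invariance(self):
        pairs = [("c1", "T1"), ("c2", "T2"), ("c1", "T3"), ("c3", "T1")]
        a = build_bipartite_network(_ct(pairs))
        b = build_bipartite_network(_ct(list(reversed(pairs))))
        assert a == b

    def test_no_pp_edges(self, study):
        net = build_bipartite_network(study.compound_targets)
        assert all(d["kind"] == "ct" for _, _, d in net.graph.edges(data=True))


class TestExpansion:
    TRIANGLE = [("A", "B", 0.9), ("A", "C", 0.9), ("B", "C", 0.9)]

    def test_induction_includes_neighbor_neighbor_edges(self):
        net = expand_with_interactors(["A"], _edges(self.TRIANGLE), min_seed_links=1)
        assert net.nodes() == {"A", "B", "C"}
        assert len(net.edges()) == 3  # B–C included by induction

    def test_min_seed_links_two_empties_the_star(self):
        with pytest.warns(UserWarning):
            net = expand_with_interactors(["A"], _edges(self.TRIANGLE), min_seed_links=2)
        assert net.n_nodes() == 0

    def test_empty_seed_set_rejected(self):
        with pytest.raises(UsageError):
            expand_with_interactors([], _edges(self.TRIANGLE))

    @pytest.mark.parametrize("min_links", [1, 2, 3])
    def test_matches_naive_double_loop(self, min_links):
        rng = np.random.default_rng(min_links)
        nodes = [f"P{i:03d}" for i in range(200)]
        pairs = [
            (nodes[i], nodes[j])
            for i in range(200) for j in range(i + 1, 200)
            if rng.random() < 0.015
        ]
        seeds = list(rng.choice(nodes, size=30, replace=False))
        net = expand_with_interactors(
            seeds, [InteractionEdge(a, b, 0.9) for a, b in pairs], min_links
        )
        expect_nodes, expect_edges = brute_expand(seeds, pairs, min_links)
        assert net.nodes() == expect_nodes
        assert net.edges() == {tuple(sorted(e)) for e in expect_edges
                               if e[0] in expect_nodes and e[1] in expect_nodes}

    def test_result_is_induced_subgraph_of_ppi(self):
        rng = np.random.default_rng(5)
        nodes = [f"P{i}" for i in range(60)]
        edges = [
            InteractionEdge(nodes[i], nodes[j], 0.9)
            for i in range(60) for j in range(i + 1, 60) if rng.random() < 0.08
        ]
        net = expand_with_interactors(nodes[:10], edges, 2)
        kept = net.nodes()
        expected = {e.pair for e in edges if e.protein_a in kept and e.protein_b in kept}
        assert net.edges() == expected

    def test_roles_from_reference_sets(self):
        edges = _edges([("S1", "S2", 0.9), ("S1", "X", 0.9), ("S2", "X", 0.9),
                        ("S1", "D", 0.9), ("S2", "D", 0.9)])
        net = expand_with_interactors(
            ["S1", "S2"], edges, 2,
            compound_targets=["S1", "S2"], disease_targets=["D", "S2"],
        )
        assert net.role("S1") == ROLE_COMPOUND_TARGET
        assert net.role("S2") == ROLE_SHARED_TARGET
        assert net.role("D") == ROLE_DISEASE_TARGET
        assert net.role("X") == ROLE_OTHER


def _pp_net(nodes_roles, edges):
    net = AnnotatedNetwork()
    for n, r in nodes_roles.items():
        net.add_node(n, r)
    for a, b in edges:
        net.add_edge(a, b, kind="pp")
    return net


class TestIntersection:
    def test_idempotence(self):
        net = _pp_net({"A": ROLE_COMPOUND_TARGET, "B": ROLE_OTHER, "C": ROLE_OTHER},
                      [("A", "B"), ("B", "C")])
        both = intersect_networks(net, net)
        assert both == net

    def test_shared_triangle_survives(self):
        tri = [("A", "B"), ("B", "C"), ("A", "C")]
        a = _pp_net({n: ROLE_OTHER for n in "ABCD"}, tri + [("C", "D")])
        b = _pp_net({n: ROLE_OTHER for n in "ABCE"}, tri + [("C", "E")])
        inter = intersect_networks(a, b)
        assert inter.nodes() == {"A", "B", "C"}
        assert inter.edges() == {("A", "B"), ("B", "C"), ("A", "C")}

    def test_commutativity(self):
        a = _pp_net({n: ROLE_OTHER for n in "ABCD"},
                    [("A", "B"), ("B", "C"), ("C", "D")])
        b = _pp_net({n: ROLE_OTHER for n in "BCDE"},
                    [("B", "C"), ("C", "D"), ("D", "E")])
        assert intersect_networks(a, b) == intersect_networks(b, a)

    def test_role_merge_produces_shared(self):
        a = _pp_net({"A": ROLE_COMPOUND_TARGET, "B": ROLE_COMPOUND_TARGET},
                    [("A", "B")])
        b = _pp_net({"A": ROLE_DISEASE_TARGET, "B": ROLE_OTHER}, [("A", "B")])
        inter = intersect_networks(a, b)
        assert inter.role("A") == ROLE_SHARED_TARGET
        assert inter.role("B") == ROLE_COMPOUND_TARGET

    def test_disjoint_parents_warn_empty(self):
        a = _pp_net({"A": ROLE_OTHER, "B": ROLE_OTHER}, [("A", "B")])
        b = _pp_net({"C": ROLE_OTHER, "D": ROLE_OTHER}, [("C", "D")])
        with pytest.warns(UserWarning):
            inter = intersect_networks(a, b)
        assert inter.n_nodes() == 0

    def test_ct_networks_rejected(self):
        ct = build_bipartite_network(_ct([("c1", "T1")]))
        pp = _pp_net({"T1": ROLE_OTHER, "X": ROLE_OTHER}, [("T1", "X")])
        with pytest.raises(UsageError):
            intersect_networks(ct, pp)


def test_summarize_totals_consistent(study):
    net = build_bipartite_network(study.compound_targets, study.truth.disease_union)
    summary = summarize_network(net)
    assert sum(summary["role_counts"].values()) == summary["n_nodes"]


def test_summarize_empty_network_zeroes():
    summary = summarize_network(AnnotatedNetwork())
    assert summary == {"role_counts": {}, "n_nodes": 0, "n_edges": 0}
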