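"""Construction of the four analysis networks.

The workflow builds, in order: (1) the bipartite compound–target network;
(2) the PPI network of compound targets expanded with interacting human
proteins; (3) the analogous PPI network of disease targets; and (4) the
intersection of (2) and (3), which isolates the interactome shared by the
herb's targets and the disease's targets.  All networks are
:class:`~netpharm.model.AnnotatedNetwork` objects with per-node roles and
per-edge kinds, and isolated nodes are dropped everywhere so that node
counts match what a connected-component network figure would show.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import UsageError
from .model import (
    KIND_CT,
    KIND_PP,
    AnnotatedNetwork,
    CompoundTargetRecord,
    InteractionEdge,
    ROLE_COMPOUND,
    ROLE_COMPOUND_TARGET,
    ROLE_DISEASE_TARGET,
    ROLE_OTHER,
    ROLE_SHARED_TARGET,
    classify_role,
)


def build_bipartite_network(
    records: Sequence[CompoundTargetRecord],
    disease_targets: Iterable[str] = (),
) -> AnnotatedNetwork:
    """Connect compounds to their targets; flag targets that are also disease targets.

    Nodes are compounds plus targets; a target in ``disease_targets`` gets
    role ``shared_target``, the rest ``compound_target``.  All edges have
    kind ``ct``; the result contains no target–target edges.
    """
    disease = {g.upper() for g in disease_targets}
    net = AnnotatedNetwork()
    for r in records:
        if r.compound_id not in net.graph:
            net.add_node(r.compound_id, ROLE_COMPOUND)
        if r.target not in net.graph:
            role = ROLE_SHARED_TARGET if r.target in disease else ROLE_COMPOUND_TARGET
            net.add_node(r.target, role)
        net.add_edge(r.compound_id, r.target, kind=KIND_CT)
    return net


def expand_with_interactors(
    seed_genes: Iterable[str],
    ppi_edges: Sequence[InteractionEdge],
    min_seed_links: int = 2,
    *,
    compound_targets: Optional[Iterable[str]] = None,
    disease_targets: Optional[Iterable[str]] = None,
) -> AnnotatedNetwork:
    """Grow a PPI network around seed proteins.

    The node set is the seeds present in the PPI plus every non-seed protein
    adjacent to at least ``min_seed_links`` seeds; the edge set is the full
    induced subgraph of the (already score-filtered) PPI on that node set.
    Seeds that end up isolated are dropped.

    Roles are assigned from membership in the ``compound_targets`` and
    ``disease_targets`` reference sets (both / one / neither →
    shared_target / compound_target / disease_target / other), so an
    expansion seeded on compound targets can still surface disease targets
    recruited as interactors.  When neither set is given, seeds default to
    ``compound_target`` and interactors to ``other``.
    """
    seeds = {g.upper() for g in seed_genes}
    if not seeds:
        raise UsageError("seed set must be non-empty")
    if min_seed_links < 1:
        raise UsageError("min_seed_links must be >= 1")

    g = nx.Graph()
    for e in ppi_edges:
        g.add_edge(e.protein_a, e.protein_b, score=e.score, kind=KIND_PP)

    present_seeds = seeds & set(g.nodes)
    neighbors = {
        n
        for n in g.nodes
        if n not in seeds and sum(1 for nb in g.neighbors(n) if nb in seeds) >= min_seed_links
    }
    keep = present_seeds | neighbors
    sub = g.subgraph(keep).copy()
    sub.remove_nodes_from(list(nx.isolates(sub)))
    if sub.number_of_nodes() == 0:
        warnings.warn("expansion produced an empty network")

    comp = {s.upper() for s in compound_targets} if compound_targets is not None else None
    dis = {s.upper() for s in disease_targets} if disease_targets is not None else None
    net = AnnotatedNetwork()
    for n in sub.nodes:
        if comp is None and dis is None:
            role = ROLE_COMPOUND_TARGET if n in seeds else ROLE_OTHER
        else:
            role = classify_role(
                comp is not None and n in comp,
                dis is not None and n in dis,
            )
        net.add_node(n, role)
    for a, b, d in sub.edges(data=True):
        net.add_edge(a, b, kind=KIND_PP, score=d.get("score"))
    return net


_COMPOUNDISH = {ROLE_COMPOUND_TARGET, ROLE_SHARED_TARGET}
_DISEASEISH = {ROLE_DISEASE_TARGET, ROLE_SHARED_TARGET}


def intersect_networks(net_a: AnnotatedNetwork, net_b: AnnotatedNetwork) -> AnnotatedNetwork:
    """Intersect two PPI networks on nodes and edges, merging roles.

    A node survives if present in both parents; an edge survives if present
    in both parents with both endpoints surviving.  The merged role reflects
    the union of what the parents knew: compound-target in either parent and
    disease-target in the other (or either) → shared_target; otherwise
    compound_target, disease_target, or other.  Isolated survivors are
    dropped.
    """
    for net in (net_a, net_b):
        if any(d.get("kind") == KIND_CT for _, _, d in net.graph.edges(data=True)):
            raise UsageError("intersection is defined for pp-edge networks only")

    common_nodes = net_a.nodes() & net_b.nodes()
    if not common_nodes:
        warnings.warn("networks share no nodes; intersection is empty")
    common_edges = net_a.edges() & net_b.edges()

    net = AnnotatedNetwork()
    for n in common_nodes:
        ra, rb = net_a.role(n), net_b.role(n)
        is_comp = ra in _COMPOUNDISH or rb in _COMPOUNDISH
        is_dis = ra in _DISEASEISH or rb in _DISEASEISH
        net.add_node(n, classify_role(is_comp, is_dis))
    for a, b in common_edges:
        if a in common_nodes and b in common_nodes:
            score_a = net_a.graph.edges[a, b].get("score")
            net.add_edge(a, b, kind=KIND_PP, score=score_a)
    return net.drop_isolates()


def summarize_network(network: AnnotatedNetwork) -> dict:
    """Role-count record: counts per role plus node and edge totals.

    The totals always equal the sum of the per-role counts — the same
    bookkeeping a figure legend prints ("X nodes (a compounds, b compound
    targets, c shared targets) and Y edges").
    """
    counts = network.role_counts()
    return {
        "role_counts": counts,
        "n_nodes": network.n_nodes(),
        "n_edges": network.n_edges(),
    }
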