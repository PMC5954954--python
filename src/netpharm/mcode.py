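"""Molecular Complex Detection (MCODE): dense-module discovery in PPI networks.

The algorithm has three stages:

1. **Vertex weighting.**  For each vertex ``v`` with degree at least
   ``degree_cutoff``, take the subgraph induced by its closed neighbourhood
   ``N[v]``, find the highest k-core of that subgraph, and set
   ``weight(v) = k_max * density(highest k-core)`` where density is
   ``2E / (V (V - 1))``.  Vertices below the degree cutoff weigh 0.  The
   weight is high exactly when the vertex sits inside a locally dense,
   cohesive region — it is robust to single high-degree hubs, unlike a plain
   clustering coefficient.

2. **Complex prediction.**  Repeatedly seed from the highest-weight unused
   vertex and grow outward (breadth-first, to ``max_depth``), admitting a
   neighbour whose weight exceeds ``seed_weight * (1 - node_score_cutoff)``.
   The comparison is always against the *original seed's* weight, so the
   admission bar does not drift as the complex grows.  Every vertex joins at
   most one complex.

3. **Post-processing.**  ``haircut`` trims the complex to its 2-core
   (removing singly-connected members); ``fluff`` optionally adds
   neighbours whose closed-neighbourhood density exceeds
   ``fluff_density_cutoff``.  Complexes smaller than 2 are discarded.

The reported complex score is ``density * size``; complexes are ranked by
descending score.  All tie-breaks (equal weights, equal scores) are
lexicographic on node id so results are deterministic across runs and input
orderings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import UsageError
from .model import AnnotatedNetwork


@dataclass(frozen=True)
class McodeParams:
    """Tunable parameters; defaults mirror the standard Cytoscape plugin."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2  # the "vertex weight percentage"
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    max_depth: int = 100

    def __post_init__(self):
        if self.degree_cutoff < 1:
            raise UsageError("degree_cutoff must be >= 1")
        if not (0.0 <= self.node_score_cutoff < 1.0):
            raise UsageError("node_score_cutoff must lie in [0,1)")
        if self.k_core < 2:
            raise UsageError("k_core must be >= 2")
        if not (0.0 <= self.fluff_density_cutoff <= 1.0):
            raise UsageError("fluff_density_cutoff must lie in [0,1]")
        if self.max_depth < 1:
            raise UsageError("max_depth must be >= 1")


@dataclass
class ModuleResult:
    """One detected complex: member set, seed vertex, density, score, rank."""

    members: frozenset[str]
    seed: str
    density: float
    score: float
    rank: int = 0
    fluffed: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)


def _graph_of(network) -> nx.Graph:
    g = network.graph if isinstance(network, AnnotatedNetwork) else network
    if any(a == b for a, b in g.edges):
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    return g


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """The maximal-k k-core of ``g`` and its k (0 with an empty graph if edgeless)."""
    if g.number_of_edges() == 0:
        return 0, nx.Graph()
    core_numbers = nx.core_number(g)
    k_max = max(core_numbers.values())
    core = g.subgraph([v for v, c in core_numbers.items() if c >= k_max])
    return k_max, core


def score_vertices(network, params: McodeParams | None = None) -> dict[str, float]:
    """Stage 1: weight every vertex by the cohesiveness of its closed neighbourhood."""
    params = params or McodeParams()
    g = _graph_of(network)
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = g.subgraph([v, *g.neighbors(v)])
        k_max, core = _highest_k_core(closed)
        weights[v] = float(k_max) * _density(core)
    return weights


def find_complexes(
    network,
    weights: dict[str, float] | None = None,
    params: McodeParams | None = None,
) -> list[ModuleResult]:
    """Stage 2 + 3: seeded greedy expansion followed by haircut/fluff.

    Returns disjoint complexes ranked by descending score (``density * size``),
    ties broken by larger size, then seed id.
    """
    params = params or McodeParams()
    g = _graph_of(network)
    if weights is None:
        weights = score_vertices(g, params)

    # seeds in descending weight, lexicographic on ties — determinism
    order = sorted(g.nodes, key=lambda v: (-weights.get(v, 0.0), v))
    used: set[str] = set()
    raw: list[tuple[str, set[str]]] = []

    for seed in order:
        if seed in used or weights.get(seed, 0.0) <= 0.0:
            continue
        bar = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in sorted(frontier):
                for w in sorted(g.neighbors(u)):
                    if w in members or w in used:
                        continue
                    if weights.get(w, 0.0) > bar:
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
            depth += 1
        used |= members
        raw.append((seed, members))

    results: list[ModuleResult] = []
    claimed: set[str] = set()  # keeps complexes disjoint even under fluff
    for seed, members in raw:
        sub = g.subgraph(members).copy()
        if params.haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() < 2:
            continue
        fluffed: set[str] = set()
        if params.fluff:
            for u in sorted(sub.nodes):
                for w in sorted(g.neighbors(u)):
                    if w in sub or w in fluffed or w in used or w in claimed:
                        continue
                    closed = g.subgraph([w, *g.neighbors(w)])
                    if _density(closed) > params.fluff_density_cutoff:
                        fluffed.add(w)
        final = set(sub.nodes) | fluffed
        claimed |= final
        dens = _density(g.subgraph(final))
        results.append(
            ModuleResult(
                members=frozenset(final),
                seed=seed if seed in final else min(final),
                density=dens,
                score=dens * len(final),
                fluffed=frozenset(fluffed),
            )
        )

    results.sort(key=lambda r: (-r.score, -len(r.members), r.seed))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def complex_score(network, members) -> float:
    """Score of a candidate complex: ``density * member count`` (density = 2E/(V(V-1)))."""
    g = _graph_of(network)
    members = set(members)
    if len(members) < 2:
        raise UsageError("a complex needs at least 2 members")
    missing = members - set(g.nodes)
    if missing:
        raise UsageError(f"members not in network: {sorted(missing)}")
    sub = g.subgraph(members)
    return _density(sub) * len(members)
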