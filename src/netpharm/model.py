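"""Core domain objects of the network-pharmacology pipeline.

The pipeline moves between four kinds of data: compound→target assertions
(the edges of the bipartite drug–target network), scored protein–protein
interaction edges (STRING-style), disease-target records assembled from
several curated sources, and gene-set annotations (GO terms / KEGG
pathways).  Networks carry a role label per node mirroring the colour code
of network-pharmacology figures: compounds, compound targets, disease
targets, shared (compound ∩ disease) targets, and other interacting human
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import UsageError

# Node roles.  A node is "shared_target" exactly when it is both a compound
# target and a disease target.
ROLE_COMPOUND = "compound"
ROLE_COMPOUND_TARGET = "compound_target"
ROLE_DISEASE_TARGET = "disease_target"
ROLE_SHARED_TARGET = "shared_target"
ROLE_OTHER = "other"
ROLES = (
    ROLE_COMPOUND,
    ROLE_COMPOUND_TARGET,
    ROLE_DISEASE_TARGET,
    ROLE_SHARED_TARGET,
    ROLE_OTHER,
)

# Edge kinds: compound–target ("ct") and protein–protein ("pp").
KIND_CT = "ct"
KIND_PP = "pp"


def classify_role(is_compound_target: bool, is_disease_target: bool) -> str:
    """Role of a protein node given membership in the two reference sets."""
    if is_compound_target and is_disease_target:
        return ROLE_SHARED_TARGET
    if is_compound_target:
        return ROLE_COMPOUND_TARGET
    if is_disease_target:
        return ROLE_DISEASE_TARGET
    return ROLE_OTHER


@dataclass(frozen=True)
class CompoundTargetRecord:
    """One compound→target assertion; the edge unit of the bipartite network."""

    compound_id: str
    target: str
    source: Optional[str] = None

    def __post_init__(self):
        if not self.compound_id:
            raise UsageError("compound_id must be non-empty")
        if not self.target or any(c.isspace() for c in self.target):
            raise UsageError(f"target must be a non-empty symbol without whitespace: {self.target!r}")


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected scored PPI edge; endpoints stored in canonical (sorted) order."""

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise UsageError(f"self-interaction not allowed: {self.protein_a}")
        if not (0.0 <= self.score <= 1.0):
            raise UsageError(f"score must lie in [0,1]: {self.score}")
        # canonical unordered representation
        if self.protein_a > self.protein_b:
            a, b = self.protein_b, self.protein_a
            object.__setattr__(self, "protein_a", a)
            object.__setattr__(self, "protein_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def dedupe_edges(edges: Iterable[InteractionEdge]) -> list[InteractionEdge]:
    """Collapse duplicate unordered pairs, keeping the maximum score."""
    best: dict[tuple[str, str], InteractionEdge] = {}
    for e in edges:
        cur = best.get(e.pair)
        if cur is None or e.score > cur.score:
            best[e.pair] = e
    return list(best.values())


@dataclass(frozen=True)
class DiseaseTargetRecord:
    """A disease-associated gene as reported by one source, optionally with a literature-evidence count."""

    gene: str
    source: str
    evidence_count: Optional[int] = None

    def __post_init__(self):
        if not self.gene:
            raise UsageError("gene must be non-empty")
        if self.evidence_count is not None and self.evidence_count < 0:
            raise UsageError("evidence_count must be >= 0")


@dataclass
class DiseaseTargetSet:
    """Redundancy-free union of disease targets with per-gene source provenance.

    ``genes`` preserves first-appearance order across sources; ``provenance``
    maps each gene to the set of sources that reported it.
    """

    genes: list[str] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.provenance


@dataclass
class AnnotationCollection:
    """Gene-set annotations: term_id -> (name, category, member set), plus a background universe."""

    terms: dict[str, tuple[str, str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_terms(
        cls,
        terms: Mapping[str, tuple[str, str, Iterable[str]]],
        universe: Optional[Iterable[str]] = None,
    ) -> "AnnotationCollection":
        fixed = {}
        members_union: set[str] = set()
        for tid, (name, category, members) in terms.items():
            mset = frozenset(members)
            if not mset:
                raise UsageError(f"term {tid} has no members")
            fixed[tid] = (name, category, mset)
            members_union |= mset
        uni = frozenset(universe) if universe is not None else frozenset(members_union)
        if not members_union <= uni:
            raise UsageError("universe must contain every term member")
        return cls(terms=fixed, universe=uni)

    def categories(self) -> set[str]:
        return {cat for _, cat, _ in self.terms.values()}


class AnnotatedNetwork:
    """An undirected graph whose nodes carry a role and whose edges carry a kind.

    Thin wrapper over :class:`networkx.Graph`; node attribute ``role`` holds
    one of :data:`ROLES`, edge attributes ``kind`` (``ct``/``pp``) and
    optionally ``score``.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- construction helpers -------------------------------------------------
    def add_node(self, node: str, role: str) -> None:
        if role not in ROLES:
            raise UsageError(f"unknown role {role!r}")
        self.graph.add_node(node, role=role)

    def add_edge(self, a: str, b: str, kind: str, score: Optional[float] = None) -> None:
        if a == b:
            raise UsageError(f"self-loop not allowed: {a}")
        attrs = {"kind": kind}
        if score is not None:
            attrs["score"] = float(score)
        self.graph.add_edge(a, b, **attrs)

    # -- accessors ------------------------------------------------------------
    def role(self, node: str) -> str:
        return self.graph.nodes[node]["role"]

    def roles(self) -> dict[str, str]:
        return {n: d["role"] for n, d in self.graph.nodes(data=True)}

    def role_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for _, d in self.graph.nodes(data=True):
            counts[d["role"]] += 1
        return {r: c for r, c in counts.items() if c}

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def drop_isolates(self) -> "AnnotatedNetwork":
        g = self.graph.copy()
        g.remove_nodes_from(list(nx.isolates(g)))
        return AnnotatedNetwork(g)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotatedNetwork):
            return NotImplemented
        return (
            self.roles() == other.roles()
            and self.edges() == other.edges()
        )

    def __repr__(self) -> str:
        return f"AnnotatedNetwork({self.n_nodes()} nodes, {self.n_edges()} edges)"
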