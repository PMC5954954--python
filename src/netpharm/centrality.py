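"""Topological indices and median-threshold hub screening.

Three node centralities drive the screening: degree (incident-edge count),
betweenness (fraction of shortest paths between other node pairs passing
through the node, normalised to [0,1] by 2/((n-1)(n-2)) for undirected
graphs), and closeness.  Closeness follows one of two conventions:

``normalized``
    (n_comp - 1) / Σ distances, computed within each connected component —
    the convention on which a well-connected node scores near 1.  This is
    the default: empirical screening thresholds in the 0.4–0.5 range only
    make sense on this scale.
``raw_inverse_sum``
    1 / Σ distances within the component — the literal "inverse of the sum
    of distances" reading, which shrinks with component size.

A node is declared a hub when *every* centrality exceeds its network-wide
median (optionally scaled by a per-metric multiplier; optionally inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import UsageError
from .model import AnnotatedNetwork

METRICS = ("degree", "betweenness", "closeness")


@dataclass
class CentralityTable:
    """Per-node degree/betweenness/closeness with the per-metric medians."""

    table: pd.DataFrame  # index: node; columns: degree, betweenness, closeness
    medians: dict[str, float] = field(default_factory=dict)
    closeness_convention: str = "normalized"

    def __post_init__(self):
        if not self.medians:
            self.medians = {m: float(self.table[m].median()) for m in METRICS}

    def with_flags(self, multipliers=None, strict: bool = True) -> pd.DataFrame:
        """Return the table with a boolean ``pass`` column added."""
        hubs = set(screen_by_median(self, multipliers, strict))
        out = self.table.copy()
        out["pass"] = [n in hubs for n in out.index]
        return out


def compute_centralities(
    network: AnnotatedNetwork, closeness_convention: str = "normalized"
) -> CentralityTable:
    """Compute degree, betweenness and closeness for every node of a network.

    Betweenness uses Brandes' single-source accumulation with the standard
    2/((n-1)(n-2)) normalisation.  Closeness is computed within each
    connected component under the chosen convention (see module docstring).
    """
    if closeness_convention not in ("normalized", "raw_inverse_sum"):
        raise UsageError(f"unknown closeness convention {closeness_convention!r}")
    g = network.graph
    if g.number_of_edges() == 0:
        raise UsageError("network must have at least one edge")

    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)

    closeness: dict[str, float] = {}
    if closeness_convention == "normalized":
        # within-component normalisation (no Wasserman–Faust cross-component scaling)
        closeness = nx.closeness_centrality(g, wf_improved=False)
    else:
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            for node in comp:
                if len(comp) == 1:
                    closeness[node] = 0.0
                    continue
                total = sum(nx.single_source_shortest_path_length(sub, node).values())
                closeness[node] = 1.0 / total if total else 0.0

    nodes = sorted(g.nodes)
    table = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return CentralityTable(table=table, closeness_convention=closeness_convention)


def screen_by_median(
    table: CentralityTable,
    multipliers: dict[str, float] | float | None = None,
    strict: bool = True,
) -> list[str]:
    """Hub screening: keep nodes exceeding (a multiple of) every metric's median.

    ``multipliers`` maps metric name to a positive factor (default 1.0 for
    all three; a scalar applies to every metric).  With ``strict`` the
    comparison is ``value > multiplier * median`` (the convention behind
    thresholds quoted as "degree > 2×median"); otherwise ``>=``.  Hubs are
    returned sorted by degree descending, ties broken lexicographically.
    """
    if multipliers is None:
        mult = {m: 1.0 for m in METRICS}
    elif isinstance(multipliers, (int, float)):
        mult = {m: float(multipliers) for m in METRICS}
    else:
        mult = {m: float(multipliers.get(m, 1.0)) for m in METRICS}
    if any(v <= 0 for v in mult.values()):
        raise UsageError("multipliers must be > 0")

    df = table.table
    mask = pd.Series(True, index=df.index)
    for m in METRICS:
        threshold = mult[m] * table.medians[m]
        mask &= (df[m] > threshold) if strict else (df[m] >= threshold)
    hubs = df[mask]
    # stable sort on degree desc; lexicographic tie-break via pre-sorted index
    order = hubs.loc[sorted(hubs.index)].sort_values("degree", ascending=False, kind="stable")
    return list(order.index)


def write_centrality_table(
    table: CentralityTable,
    network: AnnotatedNetwork,
    path,
    multipliers=None,
    strict: bool = True,
) -> None:
    """Write the per-node table as TSV: node, role, degree, betweenness, closeness, pass."""
    flagged = table.with_flags(multipliers, strict)
    flagged.insert(0, "role", [network.role(n) for n in flagged.index])
    flagged.to_csv(path, sep="\t", float_format="%.10g")
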