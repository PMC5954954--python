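"""Readers and writers for every external format the pipeline touches.

Formats handled: compound–target tables (TSV/CSV), STRING protein-links
edge lists (whitespace-delimited ``protein1 protein2 combined_score``,
scores on the unit or permille scale), one-TSV-per-source disease-target
lists, GMT gene-set files, and network exports (SIF / GraphML / edge TSV)
with a companion node-attribute table.

Gene symbols are case-folded to uppercase at read time so that targets
reported in mixed styles join consistently; symbols are otherwise treated
as opaque strings (no identifier-mapping service is consulted).
"""

from __future__ import annotations

import csv
import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx

from .errors import FormatError, UsageError
from .model import (
    KIND_CT,
    KIND_PP,
    AnnotatedNetwork,
    AnnotationCollection,
    CompoundTargetRecord,
    DiseaseTargetRecord,
    InteractionEdge,
    ROLE_OTHER,
    dedupe_edges,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

_COMPOUND_COLS = ("compound", "compound_id", "compound_name", "molecule")
_TARGET_COLS = ("target", "target_gene", "gene", "gene_symbol", "symbol")
_SOURCE_COLS = ("source", "provenance", "database")


def _find_column(header: list[str], candidates: tuple[str, ...], what: str, path: PathLike) -> int:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand in lowered:
            return lowered.index(cand)
    raise FormatError(
        f"{path}: no {what} column found; expected one of {candidates}, got {header}"
    )


def read_compound_target_table(path: PathLike, dialect: str = "auto") -> list[CompoundTargetRecord]:
    """Read a compound–target table; returns validated, de-duplicated records.

    Parameters
    ----------
    path
        TSV or CSV file with a header naming a compound column and a target
        column (an optional source column is carried through).
    dialect
        ``"auto"`` sniffs tab vs comma from the header line; ``"tsv"`` /
        ``"csv"`` force a delimiter.

    Target symbols are uppercased; exact duplicate (compound, target) pairs
    are dropped, keeping first occurrence so row order is preserved.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        warnings.warn(f"{path}: empty compound-target file")
        return []
    if dialect == "auto":
        first = text.splitlines()[0]
        delim = "\t" if "\t" in first else ","
    elif dialect == "tsv":
        delim = "\t"
    elif dialect == "csv":
        delim = ","
    else:
        raise UsageError(f"unknown dialect {dialect!r}")

    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    header = rows[0]
    ci = _find_column(header, _COMPOUND_COLS, "compound", path)
    ti = _find_column(header, _TARGET_COLS, "target", path)
    try:
        si: Optional[int] = _find_column(header, _SOURCE_COLS, "source", path)
    except FormatError:
        si = None

    records: list[CompoundTargetRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) <= max(ci, ti):
            raise FormatError(f"{path}: row {lineno} has too few fields")
        compound = row[ci].strip()
        target = row[ti].strip().upper()
        if not compound:
            raise FormatError(f"{path}: row {lineno}: empty compound id")
        if not target:
            raise FormatError(f"{path}: row {lineno}: empty target symbol")
        if any(c.isspace() for c in target):
            raise FormatError(f"{path}: row {lineno}: target contains whitespace: {target!r}")
        key = (compound, target)
        if key in seen:
            continue
        seen.add(key)
        source = row[si].strip() or None if si is not None and len(row) > si else None
        records.append(CompoundTargetRecord(compound, target, source))
    return records


def read_ppi_edges(
    path: PathLike,
    score_scale: str = "auto",
    min_score: float = 0.0,
) -> list[InteractionEdge]:
    """Read a STRING-style protein-links file into filtered interaction edges.

    Lines are whitespace-delimited ``protein1 protein2 combined_score``; a
    header line is recognised and skipped.  ``score_scale`` is ``"unit"``
    (real scores in [0,1]), ``"permille"`` (STRING's integer 0–999 scale,
    normalised by dividing by 1000 so 700 ↔ 0.700), or ``"auto"`` (permille
    if any score exceeds 1, unit otherwise).

    Edges with score strictly greater than ``min_score`` are kept (the
    high-confidence convention is ``min_score=0.7`` with a strict
    comparison).  Self-loops are dropped; duplicate unordered pairs collapse
    to the maximum score.
    """
    if score_scale not in ("auto", "unit", "permille"):
        raise UsageError(f"unknown score_scale {score_scale!r}")
    path = Path(path)
    raw: list[tuple[str, str, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: expected 3 whitespace-delimited fields")
        a, b, s = parts[0], parts[1], parts[2]
        if lineno == 1 and not _is_number(s):
            continue  # header line
        if not _is_number(s):
            raise FormatError(f"{path}: line {lineno}: non-numeric score {s!r}")
        raw.append((a.upper(), b.upper(), float(s)))

    if not raw:
        warnings.warn(f"{path}: no PPI edges read")
        return []

    max_seen = max(s for _, _, s in raw)
    if score_scale == "auto":
        scale = "permille" if max_seen > 1.0 else "unit"
    else:
        scale = score_scale
    if scale == "permille":
        if max_seen <= 1.0:
            raise FormatError(
                f"{path}: file declared permille but every score <= 1 — scale ambiguous"
            )
        if max_seen > 999:
            raise FormatError(f"{path}: permille score out of range: {max_seen}")
    else:
        if max_seen > 1.0:
            raise FormatError(f"{path}: unit-scale score out of range: {max_seen}")

    edges = []
    for a, b, s in raw:
        if a == b:
            continue
        score = s / 1000.0 if scale == "permille" else s
        if score > min_score:
            edges.append(InteractionEdge(a, b, score))
    return dedupe_edges(edges)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_disease_targets(path: PathLike, source: Optional[str] = None) -> list[DiseaseTargetRecord]:
    """Read one disease-target source file: ``gene [TAB evidence_count]`` per line.

    A header line starting with ``gene`` is skipped.  ``source`` defaults to
    the file stem.
    """
    path = Path(path)
    source = source if source is not None else path.stem
    records = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        gene = parts[0].strip().upper()
        if lineno == 1 and gene.lower() in ("gene", "gene_symbol", "symbol", "target"):
            continue
        if not gene:
            raise FormatError(f"{path}: line {lineno}: empty gene symbol")
        evidence: Optional[int] = None
        if len(parts) > 1 and parts[1].strip():
            try:
                evidence = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad evidence count {parts[1]!r}") from exc
        records.append(DiseaseTargetRecord(gene, source, evidence))
    return records


def read_gene_sets(path: PathLike) -> AnnotationCollection:
    """Parse a GMT file into an annotation collection.

    Each line is ``term_id TAB description TAB gene [TAB gene ...]``.  A
    ``category=<x>`` token anywhere in the description assigns the term's
    category (e.g. a KEGG top-level class); terms without one fall in
    ``"unassigned"``.  The background universe is the union of all members.
    """
    path = Path(path)
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: GMT line needs >= 3 tab-separated fields")
        term_id, description = parts[0], parts[1]
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise FormatError(f"{path}: line {lineno}: term {term_id} has an empty gene list")
        category = "unassigned"
        name_tokens = []
        for tok in description.split():
            if tok.startswith("category="):
                category = tok.split("=", 1)[1]
            else:
                name_tokens.append(tok)
        terms[term_id] = (" ".join(name_tokens) or term_id, category, genes)
    return AnnotationCollection.from_terms(terms)


def write_gene_sets(collection: AnnotationCollection, path: PathLike) -> None:
    """Write an annotation collection as GMT (category embedded in the description)."""
    path = Path(path)
    with path.open("w") as fh:
        for tid in sorted(collection.terms):
            name, category, members = collection.terms[tid]
            desc = f"{name} category={category}"
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

_KIND_RELATION = {KIND_PP: "pp", KIND_CT: "ct"}


def _node_table_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".nodes.tsv")


def write_network(network: AnnotatedNetwork, path: PathLike, format: str = "sif") -> Path:
    """Export a network plus a companion node-attribute TSV.

    ``format`` is ``sif`` (Cytoscape simple-interaction lines using relation
    ``pp`` for protein–protein and ``ct`` for compound–target edges),
    ``graphml``, or ``edge_tsv`` (node_a, node_b, kind, score).  The node
    attribute companion ``<path>.nodes.tsv`` lists ``node TAB role`` and is
    what makes the export round-trippable (isolated nodes and roles are not
    representable in SIF itself).  Returns the companion path.
    """
    path = Path(path)
    if network is None:
        raise UsageError("network must not be None")
    if format == "sif":
        with path.open("w") as fh:
            for a, b, d in sorted(network.graph.edges(data=True)):
                fh.write(f"{a}\t{_KIND_RELATION[d.get('kind', KIND_PP)]}\t{b}\n")
    elif format == "graphml":
        nx.write_graphml(network.graph, path)
    elif format == "edge_tsv":
        with path.open("w") as fh:
            fh.write("node_a\tnode_b\tkind\tscore\n")
            for a, b, d in sorted(network.graph.edges(data=True)):
                score = d.get("score", "")
                fh.write(f"{a}\t{b}\t{d.get('kind', KIND_PP)}\t{score}\n")
    else:
        raise UsageError(f"unknown network format {format!r}")

    node_path = _node_table_path(path)
    with node_path.open("w") as fh:
        fh.write("node\trole\n")
        for n in sorted(network.graph.nodes):
            fh.write(f"{n}\t{network.role(n)}\n")
    return node_path


def read_network(path: PathLike, format: str = "sif") -> AnnotatedNetwork:
    """Read a network written by :func:`write_network` (with its node companion)."""
    path = Path(path)
    node_path = _node_table_path(path)
    roles: dict[str, str] = {}
    if node_path.exists():
        for line in node_path.read_text().splitlines()[1:]:
            if line.strip():
                node, role = line.split("\t")
                roles[node] = role

    net = AnnotatedNetwork()
    for node, role in roles.items():
        net.add_node(node, role)

    if format == "sif":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: SIF line needs 3 fields")
            a, rel, b = parts
            kind = KIND_CT if rel == "ct" else KIND_PP
            _ensure_node(net, a, roles)
            _ensure_node(net, b, roles)
            net.add_edge(a, b, kind=kind)
    elif format == "graphml":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            net.add_node(n, roles.get(n, d.get("role", ROLE_OTHER)))
        for a, b, d in g.edges(data=True):
            net.add_edge(a, b, kind=d.get("kind", KIND_PP), score=d.get("score"))
    elif format == "edge_tsv":
        for lineno, line in enumerate(path.read_text().splitlines()[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}: line {lineno}: edge TSV line needs 4 fields")
            a, b, kind, score = parts
            _ensure_node(net, a, roles)
            _ensure_node(net, b, roles)
            net.add_edge(a, b, kind=kind, score=float(score) if score else None)
    else:
        raise UsageError(f"unknown network format {format!r}")
    return net


def _ensure_node(net: AnnotatedNetwork, node: str, roles: dict[str, str]) -> None:
    if node not in net.graph:
        net.add_node(node, roles.get(node, ROLE_OTHER))


def write_compound_target_table(records: Iterable[CompoundTargetRecord], path: PathLike) -> None:
    """Write compound–target records as TSV (the dialect :func:`read_compound_target_table` reads)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("compound\ttarget\tsource\n")
        for r in records:
            fh.write(f"{r.compound_id}\t{r.target}\t{r.source or ''}\n")


def write_ppi_edges(edges: Iterable[InteractionEdge], path: PathLike, score_scale: str = "unit") -> None:
    """Write interaction edges in the STRING protein-links dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for e in sorted(edges, key=lambda e: e.pair):
            if score_scale == "permille":
                fh.write(f"{e.protein_a} {e.protein_b} {round(e.score * 1000)}\n")
            else:
                fh.write(f"{e.protein_a} {e.protein_b} {e.score:.6f}\n")


def write_disease_targets(records: Iterable[DiseaseTargetRecord], path: PathLike) -> None:
    """Write one source's disease-target records as ``gene [TAB evidence]`` TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\tevidence_count\n")
        for r in records:
            ev = "" if r.evidence_count is None else str(r.evidence_count)
            fh.write(f"{r.gene}\t{ev}\n")
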