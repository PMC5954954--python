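"""Disease-target assembly: per-source evidence screening and redundancy-free union.

Disease-associated genes typically arrive from several curated resources
(e.g. a therapeutic-target database, a Mendelian-disease catalogue, a
pharmacogenomics knowledgebase, and a literature-mining engine).  Sources
backed by text mining carry a per-gene publication count; those records are
screened with an inclusive evidence threshold (keep genes reported by at
least ``min_evidence`` papers) before the per-source lists are merged into
a single redundancy-free target set with provenance.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

from .errors import UsageError
from .model import DiseaseTargetRecord, DiseaseTargetSet


def filter_by_evidence(
    records: Iterable[DiseaseTargetRecord], min_evidence: int
) -> list[DiseaseTargetRecord]:
    """Keep records whose evidence count is at least ``min_evidence`` (inclusive).

    Records without an evidence count are kept only when ``min_evidence`` is 0
    (an unscreened source).
    """
    if min_evidence < 0:
        raise UsageError("min_evidence must be >= 0")
    kept = []
    for r in records:
        if r.evidence_count is None:
            if min_evidence == 0:
                kept.append(r)
        elif r.evidence_count >= min_evidence:
            kept.append(r)
    return kept


def merge_target_sources(
    per_source_lists: Mapping[str, Sequence[str]] | Sequence[Sequence[DiseaseTargetRecord]],
) -> DiseaseTargetSet:
    """Union per-source gene lists into a redundancy-free disease-target set.

    Accepts either a mapping ``source -> gene list`` or a sequence of
    per-source :class:`DiseaseTargetRecord` lists.  Output order is
    first-appearance order across sources in the given source order;
    provenance records every source that reported each gene.
    """
    pairs: list[tuple[str, str]] = []  # (source, gene)
    if isinstance(per_source_lists, Mapping):
        for source, genes in per_source_lists.items():
            for g in genes:
                pairs.append((source, g.upper()))
    else:
        for records in per_source_lists:
            for r in records:
                pairs.append((r.source, r.gene.upper()))
    if not pairs and not len(per_source_lists):
        raise UsageError("at least one source list is required")

    result = DiseaseTargetSet()
    for source, gene in pairs:
        if gene not in result.provenance:
            result.genes.append(gene)
            result.provenance[gene] = set()
        result.provenance[gene].add(source)
    if not result.genes:
        warnings.warn("merged disease-target set is empty")
    return result
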