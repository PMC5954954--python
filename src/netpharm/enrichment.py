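"""Over-representation analysis of gene lists against GO/KEGG-style annotations.

For a query of ``n`` genes drawn from a background of ``N`` annotated
genes, a term annotating ``K`` background genes, and an observed overlap of
``k`` genes, significance is the hypergeometric upper tail

    p = P(X >= k),  X ~ Hypergeom(N, K, n).

The EASE convention (the more conservative variant popularised by DAVID)
substitutes ``k - 1`` for ``k``.  P-values are adjusted per annotation
category with the Benjamini–Hochberg step-up procedure; a term passes when
both ``p`` and FDR fall below their thresholds (defaults 0.01 / 0.01).  The
*rich factor* reported alongside is ``k / K`` — the fraction of a term's
annotated genes hit by the query, the dot-size quantity of enrichment dot
plots.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .model import AnnotationCollection


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overlap counts, statistics and pass flag."""

    term_id: str
    term_name: str
    category: str
    N: int  # background size
    K: int  # term size within background
    n: int  # query size within background
    k: int  # overlap
    p_value: float
    fdr: float
    rich_factor: float
    passes: bool
    overlap_genes: frozenset[str] = frozenset()


def hypergeom_tail(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``ease=True`` applies the EASE-score convention: the overlap is
    decremented by one (floored at zero) before the tail is taken.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise UsageError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    kk = max(k - 1, 0) if ease else k
    if kk == 0:
        return 1.0
    # sf(kk-1) = P(X >= kk)
    return float(stats.hypergeom.sf(kk - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise UsageError("p-values must lie in (0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(
    query_genes: Iterable[str],
    annotation: AnnotationCollection,
    background: Optional[Iterable[str]] = None,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.01,
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation in a query gene list.

    The background defaults to the annotation's universe and the query is
    intersected with it first.  Terms with zero overlap are not reported.
    FDR is computed within each annotation category separately (GO terms and
    KEGG pathways are corrected as different families).  Results are sorted
    by p-value ascending, ties broken by term id.
    """
    bg = frozenset(g.upper() for g in background) if background is not None else annotation.universe
    query = {g.upper() for g in query_genes} & bg
    if not query:
        raise UsageError("query has no genes in the background")
    N = len(bg)
    n = len(query)

    rows = []
    for term_id in sorted(annotation.terms):
        name, category, members = annotation.terms[term_id]
        members_bg = members & bg
        K = len(members_bg)
        overlap = members_bg & query
        k = len(overlap)
        if k == 0 or K == 0:
            continue
        p = hypergeom_tail(k, K, n, N, ease=ease)
        rows.append((term_id, name, category, K, k, overlap, p))

    # BH within category
    fdr_by_term: dict[str, float] = {}
    for category in {r[2] for r in rows}:
        cat_rows = [r for r in rows if r[2] == category]
        adjusted = bh_fdr([r[6] for r in cat_rows])
        for r, q in zip(cat_rows, adjusted):
            fdr_by_term[r[0]] = q

    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=name,
            category=category,
            N=N,
            K=K,
            n=n,
            k=k,
            p_value=p,
            fdr=fdr_by_term[term_id],
            rich_factor=k / K,
            passes=(p < p_threshold) and (fdr_by_term[term_id] < fdr_threshold),
            overlap_genes=frozenset(overlap),
        )
        for term_id, name, category, K, k, overlap, p in rows
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def classify_categories(
    results: Iterable[EnrichmentResult],
    category_map: Optional[Mapping[str, str]] = None,
) -> Counter:
    """Tally passing terms per top-level class.

    ``category_map`` maps term_id to a top-level class (e.g. a KEGG pathway
    to "human diseases"); when omitted, each result's own category label is
    used.  Unmapped passing terms fall in ``"unassigned"``.  Counts sum to
    the number of passing terms.
    """
    tally: Counter = Counter()
    for r in results:
        if not r.passes:
            continue
        if category_map is None:
            tally[r.category] += 1
        else:
            tally[category_map.get(r.term_id, "unassigned")] += 1
    return tally


def results_table(results: Sequence[EnrichmentResult]):
    """Long-format DataFrame of enrichment results (dot-plot ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "rich_factor": [r.rich_factor for r in results],
            "pass": [r.passes for r in results],
        }
    )
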