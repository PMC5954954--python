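"""Hypergeometric over-representation analysis of a gene module.

For a query of n genes out of an N-gene background, a term with K annotated
genes and k of them in the query is scored by the upper-tail probability
P(X >= k); BH-FDR is applied within each annotation category, and a term
passes at p < 0.01 and FDR < 0.01.  The rich factor k/K is the fraction of
the term hit by the query.
"""

from netpharm import enrich, generate_ppi, generate_annotations

edges, planted, _ = generate_ppi(seed=1)
universe = sorted({n for e in edges for n in e.pair})
annotations, enriched_truth = generate_annotations(
    n_terms=60, enriched_modules=[sorted(m) for m in planted],
    enrichment_fraction=0.8, universe=universe, seed=1)

query = sorted(planted[0])
results = enrich(query, annotations)
print(f"query: the {len(query)} members of planted module 1; "
      f"background: {len(annotations.universe)} genes, {len(annotations.terms)} terms")
print("top terms (term, category, k/K, p, FDR, rich factor, passes):")
for r in results[:5]:
    print(f"  {r.term_id:10s} {r.category:6s} {r.k}/{r.K}  p={r.p_value:.2e} "
          f"fdr={r.fdr:.2e} rich={r.rich_factor:.2f} {'PASS' if r.passes else '-'}")
print(f"truth: the term loaded with module 1 is {enriched_truth[0][0]}")
# The planted term should rank first with a vanishing p-value; background
# terms hit only by chance should not pass the 0.01/0.01 screen.
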