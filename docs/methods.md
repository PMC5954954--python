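# Methods

This note documents the models and procedures implemented in `netpharm`,
the parameters that matter, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Input conventions

**Compound–target tables** are TSV/CSV with named compound and target
columns. Gene symbols are case-folded to uppercase at read time, because
real studies mix symbol styles (TP53, p27^Kip1); symbols are otherwise
opaque strings — no identifier-mapping service is consulted, so
cross-source joins require consistent naming upstream.

**PPI edge lists** follow the STRING protein-links dialect
(`protein1 protein2 combined_score`). Scores on the integer permille
scale (0–999) are normalised by dividing by 1000, matching the common
convention that 700 ↔ 0.700. The confidence filter keeps edges with score
*strictly greater than* the threshold (default 0.7, the high-confidence
convention). Duplicate unordered pairs collapse to the maximum score —
conservative toward inclusion and deterministic; self-loops are dropped.

**Disease-target sources** are one TSV per source (`gene [TAB
evidence_count]`). The evidence filter is *inclusive* (`count >=
min_evidence`, default 20), mirroring screening rules phrased as "reported
by at least N papers". Records without a count survive only at
`min_evidence = 0`, so an unscreened source must be declared as such. The
union preserves first-appearance order across sources and keeps per-gene
provenance.

**Annotations** are GMT lines; a `category=<x>` token in the description
column assigns each term to a correction family (e.g. GO_BP vs KEGG).

## Networks

All networks are undirected, role-labelled graphs. Roles partition the
node set: `compound`, `compound_target`, `disease_target`,
`shared_target` (a protein that is both a compound target and a disease
target), `other` (an interacting human protein that is neither).

The PPI expansion around a seed set keeps the seeds present in the
filtered PPI plus every non-seed protein adjacent to at least
`min_seed_links` seeds (default 2), and takes the *induced subgraph* on
that node set — neighbour–neighbour edges are kept, not only seed spokes.
The default of 2 reflects that single-link neighbours of a large seed set
are mostly noise at high-confidence score thresholds; the parameter is
exposed because published studies rarely state their inclusion rule.
Isolated nodes are dropped in every construction, so node counts match
what a connected-component network figure shows; medians and screening are
computed on the resulting node table.

Intersection keeps nodes present in both parents and edges present in both
parents; when both parents are built from the same filtered PPI this
equals the induced rule, but it stays well-defined if the parents used
different thresholds. Roles merge by union of evidence: compound-target
in either parent plus disease-target in either parent → shared target.

## Centralities and hub screening

Degree is the incident-edge count. Betweenness is the standard
shortest-path count Σ_{s≠t≠v} σ_st(v)/σ_st, computed with Brandes'
algorithm and normalised by 2/((n−1)(n−2)). Closeness has two
conventions:

* `normalized` (default): (n_c − 1) / Σ distances within the node's
  connected component of size n_c, giving values in (0, 1]. Empirical
  screening thresholds in the 0.4–0.5 range only make sense on this
  scale, which is why it is the default.
* `raw_inverse_sum`: the literal 1 / Σ distances, which shrinks with
  component size; provided for completeness.

A node is a hub when **every** metric satisfies `value > multiplier ×
median` (strict, default multiplier 1.0 per metric; `strict=False` gives
`>=`). Raising any multiplier can only shrink the hub set. Published
screens sometimes quote a degree threshold of twice the median together
with median thresholds for the other two metrics; that is expressible
here as `multipliers={"degree": 2.0}` rather than hard-coded. Hubs are
reported sorted by degree descending, ties broken lexicographically, so
output order is reproducible.

## MCODE

The implementation follows the classical molecular-complex-detection
algorithm, with the Cytoscape plugin's defaults (degree cutoff 2, node
score cutoff 0.2, haircut on, fluff off, max depth 100):

1. *Vertex weighting.* weight(v) = k_max × density of the highest k-core
   of v's closed neighbourhood; density is 2E/(V(V−1)) (self-loops are
   removed at input). Vertices under the degree cutoff weigh 0.
2. *Complex prediction.* Seed from the highest-weight unused vertex;
   breadth-first expansion admits a neighbour whose weight strictly
   exceeds seed_weight × (1 − node_score_cutoff). The bar is always
   relative to the *original seed*, so it does not drift as the complex
   grows. Each vertex joins at most one complex.
3. *Post-processing.* Haircut trims the complex to its 2-core; fluff
   (off by default) adds unclaimed neighbours whose closed-neighbourhood
   density exceeds the fluff cutoff, without ever sharing nodes between
   complexes. Complexes below size 2 are discarded.

Scores are density × size (a k-clique scores k); ranking is by descending
score, then size, then seed id. All tie-breaks (equal weights, equal
scores) are lexicographic on node id, making results independent of input
ordering — a property the tests assert.

A consequence of the weight-bar expansion worth knowing: two equally
dense, equally sized complexes joined by a single bridge edge merge into
one complex, because the bridge endpoints carry full complex weight. Only
a weight gap (e.g. different complex sizes) keeps them apart. This is the
algorithm's documented behaviour, not an implementation artefact.

The pipeline clusters the pp-edge network only; compounds never enter the
clustered graph and are re-attached to modules at reporting time.

## Enrichment

For a query of n genes in a background of N annotated genes and a term
with K members in the background and k in the query, significance is the
hypergeometric upper tail P(X ≥ k). The EASE convention (k → k − 1,
floored at 0) is available for compatibility with DAVID-style reports but
the plain tail is the default. The background defaults to the GMT's
universe (union of all members) and is overridable; terms with zero
overlap are not reported, since they carry p = 1 and make the FDR
denominator ambiguous. FDR is Benjamini–Hochberg, applied within each
annotation category separately (GO terms and KEGG pathways are distinct
families). A term passes at p < 0.01 and FDR < 0.01 (both configurable).
The rich factor k/K is reported for dot-plot-style summaries, and passing
pathways can be tallied into top-level classes via a user-supplied
pathway→class map.

Because the hypergeometric law is discrete, the null rate of `p < α` is
at most α and approaches it only when the overlap support is fine-grained.
The calibration test therefore uses large terms (800 of 4000) and large
queries (600), where the closed-form null rate of p < 0.01 is ≈0.0095;
with small terms the check would measure the discreteness of the
distribution, not the correctness of the code.

## Synthetic-study generator

The generator emulates the *structure* of a herb-versus-disease study at
its published scale, with a single master seed deriving independent
substreams per component (fully deterministic, byte-identical reruns):

* **Compound targets** (defaults: 32 compounds, 353-target pool, mean
  degree 22.91 → 733 assertions): compound degrees are lognormal
  (sigma = `skew`, default 1.5) scaled to the exact edge total, giving a
  few promiscuous hub compounds; targets are drawn per compound without
  replacement under Zipf-like popularity, so some targets are shared.
* **PPI** (defaults: 400 nodes, background edge probability 0.02, three
  planted modules of 16/10/6 nodes at intra-density 0.9): planted blocks
  are *near-regular* random subgraphs of the clique at the requested
  density — protein complexes are uniformly dense, and balanced
  intra-degrees keep a block's MCODE vertex weights homogeneous the way a
  real complex's are. (With i.i.d. per-pair planting, the binomial spread
  of intra-degrees pushes some members below the admission bar of any
  faithful MCODE, and recovery becomes a coin flip on the seed draw.)
  Planted edges score in (0.72, 0.999); a configurable fraction (default
  0.25) of background edges scores below 0.7 and is removed by the
  confidence filter.
* **Disease sources** (defaults: sizes 12/12/37/14, overlap 1/7): each
  source after the first re-reports `round(size × overlap)` previously
  seen genes; the defaults remove exactly 9 redundant records, so the
  union is 66. The last source carries evidence counts: true members
  count 20 + Poisson(12), and an equal number of decoys count below 20,
  so the ≥ 20 filter has a known pass set.
* **Annotations** (default 100 terms of 10–40 genes over the PPI
  universe): one designated term per planted module carries 80% of the
  module's members; with enrichment off the output is a null instrument.

The whole-study generator stitches these together over one gene
namespace: planted-module members are forced into the compound-target
pool, and 14 compound targets are forced into the disease pool as the
true shared targets. The truth sidecar (JSON) records planted modules,
enriched terms, shared targets, the evidence pass set, per-compound
degrees and all generator parameters.

What the generator does **not** emulate: real degree distributions of the
human interactome (background is Erdős–Rényi), biological correlation
between annotation terms (terms are independent draws, no GO DAG), score
semantics of STRING's evidence channels, or compound chemistry. Passing
tests therefore demonstrate algorithmic correctness and bookkeeping
fidelity at realistic scale — not that the pipeline's biological
conclusions on any real dataset are right.

## Problem sizes and tolerances

Tests compare centralities against exhaustive shortest-path enumeration
on graphs of up to 25 nodes (exact for degree, 1e-12 for the real-valued
metrics), hypergeometric tails against exact integer-combinatorial
summation for every admissible case with N ≤ 60 (1e-12), and MCODE
weights against a peel-based brute-force evaluation. The end-to-end runs
use the default ≈400-node synthetic study, which keeps the full suite in
the low minutes on one CPU. Null calibration uses 200 replicate queries
and a binomial 99% band around the nominal 1% rate.

## Known limitations

* MCODE has no overlapping-complex mode; fluffed nodes are claimed by the
  first complex that reaches them.
* The hub screen computes medians on the final (isolate-free) network
  table; studies that computed medians before dropping isolates will
  differ slightly.
* Cross-source gene naming is taken at face value; a mapping table must
  be applied upstream if sources use different namespaces.
* DAVID-era enrichment backgrounds are not reproducible offline; the GMT
  universe default makes term counts consistency checks rather than
  database-exact reproductions.
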