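"""Synthetic study generator: all four input kinds with known ground truth.

The generator emulates the structure of a herb-versus-disease network
pharmacology study so that every pipeline stage can be tested end to end
without database downloads:

* a bipartite compound–target table with heavy-tailed compound degrees (a
  few promiscuous hub compounds, as herbal ingredient sets show),
* a scored PPI edge list with planted dense modules in a sparse random
  background, scores arranged so the high-confidence (>0.7) filter removes
  a configurable slice of background edges but keeps planted ones,
* several disease-target source lists with controlled overlap (one source
  carries literature-evidence counts so the evidence filter has a known
  pass set),
* GMT annotations in which designated terms are genuinely enriched in the
  planted modules.

Defaults are sized to the study scale this pipeline addresses: 32
compounds with a mean of ≈22.9 targets each (≈733 bipartite edges), a
≈400-node PPI with three planted modules, and four disease sources of
12/12/37/14 genes whose redundancy-free union is 66.

A single master seed derives independent substreams for each component, so
one integer reproduces an entire synthetic study byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import UsageError
from .model import CompoundTargetRecord, DiseaseTargetRecord, InteractionEdge, AnnotationCollection
from . import io as npio

DEFAULT_MODULES: tuple[tuple[int, float], ...] = ((16, 0.9), (10, 0.9), (6, 0.9))
DEFAULT_SOURCE_SIZES: tuple[int, ...] = (12, 12, 37, 14)
DEFAULT_SOURCE_OVERLAP: float = 1.0 / 7.0  # reproduces a 66-gene union from 12+12+37+14


def _rng(seed, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,)))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated study."""

    planted_modules: list[frozenset[str]] = field(default_factory=list)
    enriched_terms: dict[int, list[str]] = field(default_factory=dict)
    shared_targets: frozenset[str] = frozenset()
    evidence_pass_set: frozenset[str] = frozenset()
    disease_union: list[str] = field(default_factory=list)
    compound_degrees: dict[str, int] = field(default_factory=dict)
    low_confidence_edges: int = 0
    generator_params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "enriched_terms": {str(k): v for k, v in self.enriched_terms.items()},
            "shared_targets": sorted(self.shared_targets),
            "evidence_pass_set": sorted(self.evidence_pass_set),
            "disease_union": self.disease_union,
            "compound_degrees": self.compound_degrees,
            "low_confidence_edges": self.low_confidence_edges,
            "generator_params": self.generator_params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            planted_modules=[frozenset(m) for m in d["planted_modules"]],
            enriched_terms={int(k): v for k, v in d["enriched_terms"].items()},
            shared_targets=frozenset(d["shared_targets"]),
            evidence_pass_set=frozenset(d["evidence_pass_set"]),
            disease_union=d["disease_union"],
            compound_degrees=d["compound_degrees"],
            low_confidence_edges=d["low_confidence_edges"],
            generator_params=d["generator_params"],
            seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# compound–target table
# ---------------------------------------------------------------------------

def generate_compound_targets(
    n_compounds: int = 32,
    n_targets: int = 353,
    mean_degree: float = 22.91,
    skew: float = 1.5,
    seed: int = 0,
    target_names: Optional[Sequence[str]] = None,
) -> tuple[list[CompoundTargetRecord], dict[str, int]]:
    """Bipartite compound→target records with heavy-tailed compound degrees.

    Compound degrees are lognormal weights (sigma = ``skew``; ``skew=0``
    gives near-uniform degrees) scaled so the total edge count equals
    ``round(n_compounds * mean_degree)``.  Targets are drawn per compound
    without replacement under Zipf-like popularity weights, so some targets
    are shared between compounds.  Returns the records and the per-compound
    degree truth.
    """
    if min(n_compounds, n_targets) < 1 or mean_degree <= 0:
        raise UsageError("generator parameters must be positive")
    if mean_degree > n_targets:
        raise UsageError(f"mean_degree {mean_degree} infeasible with {n_targets} targets")
    rng = _rng(seed, 0)

    compounds = [f"CMP{i + 1:02d}" for i in range(n_compounds)]
    if target_names is None:
        targets = [f"G{i + 1:04d}" for i in range(n_targets)]
    else:
        if len(target_names) < n_targets:
            raise UsageError("target_names shorter than n_targets")
        targets = list(target_names)[:n_targets]

    total = int(round(n_compounds * mean_degree))
    weights = np.exp(skew * rng.standard_normal(n_compounds))
    degrees = np.maximum(1, np.round(weights / weights.sum() * total).astype(int))
    # distribute rounding drift onto the largest compounds, respecting bounds
    drift = total - int(degrees.sum())
    order = np.argsort(-weights)
    i = 0
    while drift != 0 and i < 10 * n_compounds:
        j = order[i % n_compounds]
        step = 1 if drift > 0 else -1
        if 1 <= degrees[j] + step <= n_targets:
            degrees[j] += step
            drift -= step
        i += 1
    degrees = np.minimum(degrees, n_targets)

    popularity = 1.0 / np.arange(1, n_targets + 1)  # Zipf-like target reuse
    popularity /= popularity.sum()
    records: list[CompoundTargetRecord] = []
    degree_truth: dict[str, int] = {}
    for c, d in zip(compounds, degrees):
        chosen = rng.choice(n_targets, size=int(d), replace=False, p=popularity)
        for t in sorted(chosen):
            records.append(CompoundTargetRecord(c, targets[int(t)], source="synthetic"))
        degree_truth[c] = int(d)
    return records, degree_truth


# ---------------------------------------------------------------------------
# scored PPI with planted modules
# ---------------------------------------------------------------------------

def generate_ppi(
    n_nodes: int = 400,
    background_p: float = 0.02,
    modules: Sequence[tuple[int, float]] = DEFAULT_MODULES,
    low_conf_fraction: float = 0.25,
    seed: int = 0,
    node_prefix: str = "G",
) -> tuple[list[InteractionEdge], list[frozenset[str]], int]:
    """Random background PPI with planted dense blocks and confidence scores.

    Background node pairs connect with probability ``background_p``; pairs
    inside a planted module connect with that module's ``intra_p``.  Planted
    edges score uniformly in (0.72, 0.999) — above the high-confidence
    threshold — while a ``low_conf_fraction`` slice of background edges
    scores in (0.15, 0.70) and is removed by a 0.7 filter.  Returns the
    scored edge list (pre-filter), the planted module node sets, and the
    number of low-confidence background edges.
    """
    sizes = [s for s, _ in modules]
    if sum(sizes) > n_nodes:
        raise UsageError("module sizes exceed n_nodes")
    if not all(0 <= p <= 1 for p in [background_p, low_conf_fraction] + [p for _, p in modules]):
        raise UsageError("probabilities must lie in [0,1]")
    rng = _rng(seed, 1)

    nodes = [f"{node_prefix}{i + 1:04d}" for i in range(n_nodes)]
    perm = rng.permutation(n_nodes)
    planted: list[frozenset[str]] = []
    pos = 0
    module_of = {}
    for idx, (size, _) in enumerate(modules):
        members = frozenset(nodes[perm[pos + j]] for j in range(size))
        for m in members:
            module_of[m] = idx
        planted.append(members)
        pos += size

    edges: list[InteractionEdge] = []
    n_low = 0
    # planted blocks: near-regular subgraphs of the clique at density intra_p
    # (protein complexes are uniformly dense; balanced intra-degrees keep the
    # block's vertex weights homogeneous, as in a real complex)
    for idx, (size, p) in enumerate(modules):
        members = sorted(planted[idx])
        pairs = [(members[i], members[j]) for i in range(size) for j in range(i + 1, size)]
        n_remove = int(round((1.0 - p) * len(pairs)))
        max_loss = int(np.ceil((1.0 - p) * (size - 1))) if size > 1 else 0
        removed: set[tuple[str, str]] = set()
        losses = {m: 0 for m in members}
        order_idx = rng.permutation(len(pairs))
        for pi in order_idx:
            if len(removed) >= n_remove:
                break
            a, b = pairs[int(pi)]
            if losses[a] < max_loss and losses[b] < max_loss:
                removed.add((a, b))
                losses[a] += 1
                losses[b] += 1
        for a, b in pairs:
            if (a, b) not in removed:
                edges.append(InteractionEdge(a, b, float(rng.uniform(0.72, 0.999))))

    for i in range(n_nodes):
        a = nodes[i]
        for j in range(i + 1, n_nodes):
            b = nodes[j]
            same = module_of.get(a) is not None and module_of.get(a) == module_of.get(b)
            if same:
                continue  # intra-module pairs handled above
            if rng.random() < background_p:
                if rng.random() < low_conf_fraction:
                    score = float(rng.uniform(0.15, 0.70))
                    n_low += 1
                else:
                    score = float(rng.uniform(0.701, 0.999))
                edges.append(InteractionEdge(a, b, score))
    return edges, planted, n_low


# ---------------------------------------------------------------------------
# disease-target sources
# ---------------------------------------------------------------------------

def generate_disease_sources(
    n_sources: int = 4,
    sizes: Sequence[int] = DEFAULT_SOURCE_SIZES,
    overlap: float = DEFAULT_SOURCE_OVERLAP,
    evidence_law: tuple[str, float] = ("poisson", 12.0),
    seed: int = 0,
    gene_pool: Optional[Sequence[str]] = None,
    evidence_source_index: int = -1,
    force_first: int = 0,
) -> tuple[list[list[DiseaseTargetRecord]], frozenset[str], list[str]]:
    """Per-source disease-target lists with controlled redundancy.

    Each source after the first re-reports ``round(size * overlap)`` genes
    already seen in earlier sources; the rest are new draws from the pool,
    so the redundancy-free union size is known exactly (``overlap=0`` gives
    the sum of the sizes; the defaults give 66 from 12+12+37+14).

    The source at ``evidence_source_index`` carries literature-evidence
    counts: its ``size`` true members count ``20 + Poisson(lam)`` papers and
    an equal number of decoy records count fewer than 20, so an inclusive
    ≥20 filter recovers exactly the true members.  Returns the per-source
    record lists, the evidence-filter pass set, and the union in
    first-appearance order.
    """
    if len(sizes) != n_sources:
        raise UsageError("len(sizes) must equal n_sources")
    if any(s < 1 for s in sizes):
        raise UsageError("source sizes must be positive")
    rng = _rng(seed, 2)
    if gene_pool is None:
        gene_pool = [f"D{i + 1:04d}" for i in range(10 * sum(sizes))]
    pool = list(gene_pool)
    if len(pool) < 2 * sum(sizes):
        raise UsageError("gene_pool too small for requested sizes")
    # the first `force_first` pool genes are guaranteed to be drawn (used by
    # the whole-study generator to plant the true compound ∩ disease targets)
    forced, rest = pool[:force_first], pool[force_first:]
    rng.shuffle(rest)
    pool = forced + rest
    pool_iter = iter(pool)

    evidence_source_index %= n_sources
    source_names = [f"source{i + 1}" for i in range(n_sources)]
    law, lam = evidence_law

    sources: list[list[DiseaseTargetRecord]] = []
    seen: list[str] = []  # union in first-appearance order
    pass_set: set[str] = set()
    for i, (name, size) in enumerate(zip(source_names, sizes)):
        n_reuse = min(int(size * overlap + 0.5), len(seen)) if i > 0 else 0
        reused = [seen[int(j)] for j in rng.choice(len(seen), size=n_reuse, replace=False)] if n_reuse else []
        fresh = [next(pool_iter) for _ in range(size - n_reuse)]
        genes = reused + fresh
        for g in fresh:
            seen.append(g)

        if i == evidence_source_index:
            if law != "poisson":
                raise UsageError(f"unknown evidence law {law!r}")
            counts = 20 + rng.poisson(lam, size=len(genes))
            records = [
                DiseaseTargetRecord(g, name, int(c)) for g, c in zip(genes, counts)
            ]
            pass_set.update(genes)
            # decoys below the threshold, filtered out downstream
            decoys = [next(pool_iter) for _ in range(size)]
            records += [
                DiseaseTargetRecord(g, name, int(c))
                for g, c in zip(decoys, rng.integers(0, 20, size=len(decoys)))
            ]
        else:
            records = [DiseaseTargetRecord(g, name) for g in genes]
        sources.append(records)
    return sources, frozenset(pass_set), seen


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    n_terms: int = 100,
    term_size_range: tuple[int, int] = (10, 40),
    enriched_modules: Sequence[Sequence[str]] = (),
    enrichment_fraction: float = 0.8,
    universe: Optional[Sequence[str]] = None,
    categories: Sequence[str] = ("GO_BP", "GO_MF", "KEGG"),
    seed: int = 0,
) -> tuple[AnnotationCollection, dict[int, list[str]]]:
    """GMT-shaped annotations with terms genuinely enriched in given modules.

    Background terms draw their members uniformly from the universe.  For
    each module in ``enriched_modules`` one designated term additionally
    carries ``round(enrichment_fraction * |module|)`` module members (filled
    up to its drawn size with random genes), so its overlap with the module
    is enriched by construction.  With ``enrichment_fraction=0`` the output
    is a null instrument for calibration checks.  Returns the collection and
    the mapping module index → enriched term ids.
    """
    if n_terms < 1 or term_size_range[0] < 1 or term_size_range[0] > term_size_range[1]:
        raise UsageError("invalid term-count or size parameters")
    if not (0.0 <= enrichment_fraction <= 1.0):
        raise UsageError("enrichment_fraction must lie in [0,1]")
    rng = _rng(seed, 3)
    if universe is None:
        universe = [f"G{i + 1:04d}" for i in range(2000)]
    universe = list(universe)
    if len(universe) < term_size_range[1]:
        raise UsageError("universe smaller than the largest term")

    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    enriched_truth: dict[int, list[str]] = {}
    lo, hi = term_size_range

    for m_idx, module in enumerate(enriched_modules):
        module = [g for g in module if g in set(universe)]
        size = max(int(rng.integers(lo, hi + 1)), len(module))
        n_loaded = int(round(enrichment_fraction * len(module)))
        loaded = [module[int(j)] for j in rng.choice(len(module), size=n_loaded, replace=False)] if n_loaded else []
        fill_pool = [g for g in universe if g not in set(loaded)]
        fill = [fill_pool[int(j)] for j in rng.choice(len(fill_pool), size=size - len(loaded), replace=False)]
        tid = f"TERM_M{m_idx + 1}"
        terms[tid] = (f"planted module {m_idx + 1} term", categories[m_idx % len(categories)], frozenset(loaded + fill))
        enriched_truth[m_idx] = [tid]

    for t in range(n_terms - len(enriched_modules)):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(universe[int(j)] for j in rng.choice(len(universe), size=size, replace=False))
        tid = f"TERM{t + 1:04d}"
        terms[tid] = (f"background term {t + 1}", categories[t % len(categories)], members)

    return AnnotationCollection.from_terms(terms, universe=universe), enriched_truth


# ---------------------------------------------------------------------------
# coherent whole-study generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete synthetic study: every pipeline input plus its ground truth."""

    compound_targets: list[CompoundTargetRecord]
    ppi_edges: list[InteractionEdge]
    disease_sources: list[list[DiseaseTargetRecord]]
    annotations: AnnotationCollection
    truth: SyntheticTruth

    def write(self, outdir) -> dict[str, Path]:
        """Write every input in the dialect the pipeline readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compound_targets": outdir / "compound_targets.tsv",
            "ppi": outdir / "ppi_links.txt",
            "annotations": outdir / "annotations.gmt",
            "truth": outdir / "truth.json",
        }
        npio.write_compound_target_table(self.compound_targets, paths["compound_targets"])
        npio.write_ppi_edges(self.ppi_edges, paths["ppi"], score_scale="permille")
        npio.write_gene_sets(self.annotations, paths["annotations"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        source_paths = []
        for i, records in enumerate(self.disease_sources):
            p = outdir / f"disease_source{i + 1}.tsv"
            npio.write_disease_targets(records, p)
            source_paths.append(p)
        paths["sources"] = source_paths
        return paths


def generate_study(
    seed: int = 0,
    n_compounds: int = 32,
    n_targets: int = 353,
    mean_degree: float = 22.91,
    ppi_nodes: int = 400,
    background_p: float = 0.02,
    modules: Sequence[tuple[int, float]] = DEFAULT_MODULES,
    low_conf_fraction: float = 0.25,
    source_sizes: Sequence[int] = DEFAULT_SOURCE_SIZES,
    source_overlap: float = DEFAULT_SOURCE_OVERLAP,
    n_terms: int = 100,
    enrichment_fraction: float = 0.8,
    n_shared_targets: int = 14,
) -> SyntheticStudy:
    """Generate a coherent study: all four inputs over one gene namespace.

    The PPI defines the protein namespace.  Compound targets are drawn
    mostly from PPI nodes (planted-module members are forced into the pool
    so the dense modules surface in the compound networks), disease sources
    draw from PPI nodes with ``n_shared_targets`` genes forced into the
    compound-target pool (the true compound ∩ disease targets), and
    annotations cover the PPI universe with one genuinely enriched term per
    planted module.
    """
    rng = _rng(seed, 4)

    ppi_edges, planted, n_low = generate_ppi(
        n_nodes=ppi_nodes, background_p=background_p, modules=modules,
        low_conf_fraction=low_conf_fraction, seed=seed,
    )
    all_nodes = [f"G{i + 1:04d}" for i in range(ppi_nodes)]

    # compound-target pool: planted members first, then other PPI nodes, then
    # extra genes outside the PPI (targets with no high-confidence interactions)
    module_members = sorted({m for mod in planted for m in mod})
    non_module = [n for n in all_nodes if n not in set(module_members)]
    rng.shuffle(non_module)
    n_extra = max(n_targets - ppi_nodes, 0)
    extras = [f"X{i + 1:04d}" for i in range(n_extra)]
    pool = (module_members + non_module + extras)[:n_targets]

    records, degree_truth = generate_compound_targets(
        n_compounds=n_compounds, n_targets=n_targets, mean_degree=mean_degree,
        seed=seed, target_names=pool,
    )
    compound_target_set = {r.target for r in records}

    # disease genes: shared targets come from compound targets inside the PPI,
    # the rest from PPI nodes not targeted by any compound
    in_ppi_targets = sorted(compound_target_set & set(all_nodes))
    shared = [in_ppi_targets[int(j)] for j in rng.choice(len(in_ppi_targets), size=min(n_shared_targets, len(in_ppi_targets)), replace=False)]
    untargeted = [n for n in all_nodes if n not in compound_target_set]
    rng.shuffle(untargeted)
    # spare non-PPI disease genes keep the pool comfortably larger than the
    # source sizes plus decoys
    spare = [f"D{i + 1:04d}" for i in range(4 * sum(source_sizes))]
    disease_pool = shared + untargeted + spare

    sources, pass_set, union = generate_disease_sources(
        sizes=source_sizes, overlap=source_overlap, seed=seed, gene_pool=disease_pool,
        force_first=len(shared),
    )

    annotations, enriched_truth = generate_annotations(
        n_terms=n_terms, enriched_modules=[sorted(m) for m in planted],
        enrichment_fraction=enrichment_fraction, universe=all_nodes, seed=seed,
    )

    truth = SyntheticTruth(
        planted_modules=planted,
        enriched_terms=enriched_truth,
        shared_targets=frozenset(shared) & frozenset(union),
        evidence_pass_set=pass_set,
        disease_union=union,
        compound_degrees=degree_truth,
        low_confidence_edges=n_low,
        generator_params={
            "n_compounds": n_compounds, "n_targets": n_targets, "mean_degree": mean_degree,
            "ppi_nodes": ppi_nodes, "background_p": background_p,
            "modules": [list(m) for m in modules], "low_conf_fraction": low_conf_fraction,
            "source_sizes": list(source_sizes), "source_overlap": source_overlap,
            "n_terms": n_terms, "enrichment_fraction": enrichment_fraction,
        },
        seed=seed,
    )
    return SyntheticStudy(records, ppi_edges, sources, annotations, truth)
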