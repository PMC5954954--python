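"""End-to-end orchestration: assemble → build networks → screen → cluster → enrich.

A single :class:`RunConfig` (loadable from a flat ``key = value`` text
file, overridable by CLI flags) drives the whole workflow and every
threshold applied is echoed to the log, so a run is auditable and exactly
reproducible.  Outputs are plain TSV / SIF / GraphML files plus a
machine-readable JSON-lines report of every node/edge/role count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as npio
from .assembly import filter_by_evidence, merge_target_sources
from .centrality import compute_centralities, screen_by_median, write_centrality_table
from .enrichment import classify_categories, enrich, results_table
from .errors import NetpharmError, PipelineError, UsageError
from .mcode import McodeParams, find_complexes
from .model import AnnotatedNetwork, KIND_CT
from .networks import (
    build_bipartite_network,
    expand_with_interactors,
    intersect_networks,
    summarize_network,
)

log = logging.getLogger("netpharm.pipeline")


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run."""

    compound_targets: str = ""
    ppi: str = ""
    sources: list[str] = field(default_factory=list)
    annotations: str = ""
    output_dir: str = "netpharm_out"

    ppi_min_score: float = 0.7
    ppi_score_scale: str = "auto"
    min_evidence: int = 20  # applied to every source that carries evidence counts
    min_seed_links: int = 2
    closeness_convention: str = "normalized"
    multiplier_degree: float = 1.0
    multiplier_betweenness: float = 1.0
    multiplier_closeness: float = 1.0
    strict: bool = True
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    mcode_max_depth: int = 100
    p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.ppi_min_score <= 1.0):
            raise UsageError("ppi_min_score must lie in [0,1]")
        for t in (self.p_threshold, self.fdr_threshold):
            if not (0.0 < t <= 1.0):
                raise UsageError("enrichment thresholds must lie in (0,1]")
        if self.min_evidence < 0:
            raise UsageError("min_evidence must be >= 0")

    @property
    def multipliers(self) -> dict[str, float]:
        return {
            "degree": self.multiplier_degree,
            "betweenness": self.multiplier_betweenness,
            "closeness": self.multiplier_closeness,
        }

    def mcode_params(self) -> McodeParams:
        return McodeParams(
            degree_cutoff=self.mcode_degree_cutoff,
            node_score_cutoff=self.mcode_node_score_cutoff,
            haircut=self.mcode_haircut,
            fluff=self.mcode_fluff,
            max_depth=self.mcode_max_depth,
        )

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat ``key = value`` config file; later kwargs override file values.

        Lists (``sources``) are comma-separated; booleans accept
        true/false/1/0/yes/no.
        """
        values: dict = {}
        text = Path(path).read_text()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise UsageError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise UsageError(f"{path}: line {lineno}: unknown config key {key!r}")
            values[key] = _coerce(value, fields[key].type)
        values.update(overrides)
        return cls(**values)

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, list):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")


def _coerce(value: str, ftype: str):
    ftype = str(ftype)
    if "list" in ftype:
        return [v.strip() for v in value.split(",") if v.strip()]
    if "bool" in ftype:
        return value.lower() in ("1", "true", "yes", "on")
    if "int" in ftype:
        return int(value)
    if "float" in ftype:
        return float(value)
    return value


@dataclass
class ReportBundle:
    """Everything one run produced, with the summary count records."""

    config: RunConfig
    disease_targets: object = None
    networks: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)
    hubs: dict = field(default_factory=dict)
    modules: list = field(default_factory=list)
    enrichment: dict = field(default_factory=dict)
    category_tally: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except NetpharmError as exc:
                if isinstance(exc, PipelineError):
                    raise
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full workflow from a config; writes outputs under ``config.output_dir``.

    Stages: read inputs, assemble disease targets (evidence filter + union),
    build the bipartite network, the two PPI expansion networks and their
    intersection, compute centralities and screen hubs on the disease and
    intersection networks, cluster the intersection network with MCODE,
    enrich each module, tally pathway categories, and write the report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ReportBundle(config=config)

    log.info("thresholds: ppi_min_score>%s (strict), min_evidence>=%s, "
             "min_seed_links=%s, multipliers=%s (strict=%s), p<%s, fdr<%s",
             config.ppi_min_score, config.min_evidence, config.min_seed_links,
             config.multipliers, config.strict, config.p_threshold, config.fdr_threshold)

    # --- read inputs --------------------------------------------------------
    records = _read_inputs_stage(config)
    ppi = _read_ppi_stage(config)
    source_records = _read_sources_stage(config)
    annotation = _read_annotations_stage(config) if config.annotations else None

    # --- assemble disease targets ------------------------------------------
    disease = _assemble_stage(config, source_records)
    report.disease_targets = disease
    log.info("disease targets: %d after union (min_evidence=%d)", len(disease), config.min_evidence)

    # --- build the four networks -------------------------------------------
    bipartite = _bipartite_stage(records, disease)
    compound_targets = sorted({r.target for r in records})
    compound_net = _expand_stage(
        "expand_compound_targets", compound_targets, ppi, config, compound_targets, disease.genes
    )
    disease_net = _expand_stage(
        "expand_disease_targets", disease.genes, ppi, config, compound_targets, disease.genes
    )
    intersection = _intersect_stage(compound_net, disease_net)
    report.networks = {
        "bipartite": bipartite,
        "compound_ppi": compound_net,
        "disease_ppi": disease_net,
        "intersection": intersection,
    }
    for name, net in report.networks.items():
        report.summaries[name] = summarize_network(net)
        npio.write_network(net, outdir / f"{name}.sif", format="sif")
        log.info("network %s: %s", name, report.summaries[name])

    # --- centrality screening ----------------------------------------------
    for name in ("disease_ppi", "intersection"):
        net = report.networks[name]
        if net.n_edges() == 0:
            report.hubs[name] = []
            continue
        table = compute_centralities(net, config.closeness_convention)
        hubs = screen_by_median(table, config.multipliers, config.strict)
        report.hubs[name] = hubs
        write_centrality_table(table, net, outdir / f"{name}.centrality.tsv",
                               config.multipliers, config.strict)
        log.info("%s: medians=%s, %d hubs", name, table.medians, len(hubs))

    # --- MCODE clustering ---------------------------------------------------
    modules = _cluster_stage(intersection, config)
    report.modules = modules
    _write_modules(modules, intersection, outdir)

    # --- enrichment ---------------------------------------------------------
    if annotation is not None:
        for m in modules:
            query = sorted(m.members)
            try:
                results = enrich(query, annotation,
                                 p_threshold=config.p_threshold,
                                 fdr_threshold=config.fdr_threshold)
            except UsageError:
                results = []
            report.enrichment[m.rank] = results
            if results:
                results_table(results).to_csv(
                    outdir / f"module{m.rank}.enrichment.tsv", sep="\t", index=False,
                    float_format="%.6g",
                )
        all_results = [r for rs in report.enrichment.values() for r in rs]
        report.category_tally = dict(classify_categories(all_results))

    _write_report(report, outdir)
    return report


@_stage("read_compound_targets")
def _read_inputs_stage(config):
    records = npio.read_compound_target_table(config.compound_targets)
    if not records:
        raise UsageError("compound-target table is empty")
    return records


@_stage("read_ppi")
def _read_ppi_stage(config):
    return npio.read_ppi_edges(config.ppi, score_scale=config.ppi_score_scale,
                               min_score=config.ppi_min_score)


@_stage("read_disease_sources")
def _read_sources_stage(config):
    return [npio.read_disease_targets(p) for p in config.sources]


@_stage("read_annotations")
def _read_annotations_stage(config):
    return npio.read_gene_sets(config.annotations)


@_stage("assemble_disease_targets")
def _assemble_stage(config, source_records):
    filtered = []
    for records in source_records:
        has_counts = any(r.evidence_count is not None for r in records)
        if has_counts:
            filtered.append(filter_by_evidence(records, config.min_evidence))
        else:
            filtered.append(records)
    return merge_target_sources(filtered)


@_stage("build_bipartite_network")
def _bipartite_stage(records, disease):
    if not records:
        raise UsageError("no compound-target records")
    return build_bipartite_network(records, disease.genes)


def _expand_stage(stage_name, seeds, ppi, config, compound_targets, disease_genes):
    try:
        return expand_with_interactors(
            seeds, ppi, config.min_seed_links,
            compound_targets=compound_targets, disease_targets=disease_genes,
        )
    except NetpharmError as exc:
        raise PipelineError(stage_name, str(exc)) from exc


@_stage("intersect_networks")
def _intersect_stage(a, b):
    return intersect_networks(a, b)


@_stage("mcode_clustering")
def _cluster_stage(intersection, config):
    # cluster the pp-edge network only; compounds are never in these networks
    pp = AnnotatedNetwork(intersection.graph.copy())
    drop = [(a, b) for a, b, d in pp.graph.edges(data=True) if d.get("kind") == KIND_CT]
    pp.graph.remove_edges_from(drop)
    return find_complexes(pp, params=config.mcode_params())


def _write_modules(modules, network, outdir: Path) -> None:
    with (outdir / "modules.tsv").open("w") as fh:
        fh.write("module_rank\tnode\trole\tseed_flag\n")
        for m in modules:
            for node in sorted(m.members):
                fh.write(f"{m.rank}\t{node}\t{network.role(node)}\t{int(node == m.seed)}\n")
    with (outdir / "modules.summary.tsv").open("w") as fh:
        fh.write("rank\tsize\tdensity\tscore\tseed\n")
        for m in modules:
            fh.write(f"{m.rank}\t{len(m.members)}\t{m.density:.6f}\t{m.score:.6f}\t{m.seed}\n")


def _write_report(report: ReportBundle, outdir: Path) -> None:
    lines = []
    for name, summary in report.summaries.items():
        lines.append(json.dumps({"record": "network_summary", "network": name, **summary},
                                sort_keys=True))
    for name, hubs in report.hubs.items():
        lines.append(json.dumps({"record": "hubs", "network": name,
                                 "n_hubs": len(hubs), "hubs": hubs}, sort_keys=True))
    for m in report.modules:
        lines.append(json.dumps({"record": "module", "rank": m.rank, "size": len(m.members),
                                 "density": round(m.density, 6), "score": round(m.score, 6),
                                 "seed": m.seed}, sort_keys=True))
    for rank, results in report.enrichment.items():
        passing = [r.term_id for r in results if r.passes]
        lines.append(json.dumps({"record": "enrichment", "module": rank,
                                 "n_terms_tested": len(results),
                                 "n_passing": len(passing), "passing": passing}, sort_keys=True))
    if report.category_tally:
        lines.append(json.dumps({"record": "category_tally",
                                 "tally": report.category_tally,
                                 "total": sum(report.category_tally.values())}, sort_keys=True))
    (outdir / "report.jsonl").write_text("\n".join(lines) + "\n")

    # human-readable summary
    text = ["netpharm run report", "==================="]
    for name, summary in report.summaries.items():
        roles = ", ".join(f"{r}={c}" for r, c in sorted(summary["role_counts"].items()))
        text.append(f"{name}: {summary['n_nodes']} nodes ({roles}), {summary['n_edges']} edges")
    for name, hubs in report.hubs.items():
        text.append(f"hubs[{name}]: {len(hubs)} -> {', '.join(hubs[:10])}"
                    + (" ..." if len(hubs) > 10 else ""))
    for m in report.modules:
        text.append(f"module {m.rank}: size={len(m.members)} density={m.density:.3f} "
                    f"score={m.score:.3f} seed={m.seed}")
    if report.category_tally:
        total = sum(report.category_tally.values())
        text.append(f"category tally ({total} passing pathways): "
                    + ", ".join(f"{k}={v}" for k, v in sorted(report.category_tally.items())))
    (outdir / "report.txt").write_text("\n".join(text) + "\n")
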