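"""Run the entire workflow from files, exactly as the CLI's run-all does.

Writes the four networks (SIF + node-attribute TSVs), centrality tables
with hub flags, MCODE module tables, per-module enrichment TSVs, and both a
human-readable and a JSON-lines run report.
"""

from pathlib import Path

from netpharm import RunConfig, generate_study, run_pipeline

workdir = Path("scratch/example_pipeline")
paths = generate_study(seed=1).write(workdir / "inputs")

config = RunConfig(
    compound_targets=str(paths["compound_targets"]),
    ppi=str(paths["ppi"]),
    sources=[str(p) for p in paths["sources"]],
    annotations=str(paths["annotations"]),
    output_dir=str(workdir / "out"),
    ppi_min_score=0.7,   # keep STRING-style edges with combined score > 0.7
    min_evidence=20,     # literature-mined genes need >= 20 supporting papers
)
report = run_pipeline(config)

for name, summary in report.summaries.items():
    print(f"{name}: {summary['n_nodes']} nodes, {summary['n_edges']} edges")
for name, hubs in report.hubs.items():
    print(f"hubs in {name}: {len(hubs)} -> {', '.join(hubs[:6])} ...")
print(f"MCODE modules: {[(m.rank, len(m.members), round(m.score, 2)) for m in report.modules]}")
print(f"full report: {workdir / 'out' / 'report.txt'}")
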