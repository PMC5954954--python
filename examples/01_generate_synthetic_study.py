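"""Generate a complete synthetic network-pharmacology study.

One seed produces every input the pipeline consumes — a compound–target
table, a scored PPI edge list with planted dense modules, four disease-
target source files (one with literature-evidence counts), and a GMT
annotation file — plus a JSON truth sidecar recording what was planted.
"""

from pathlib import Path

from netpharm import generate_study

study = generate_study(seed=1)
outdir = Path("scratch/example_study")
paths = study.write(outdir)

print(f"compound-target records : {len(study.compound_targets)} "
      f"over {len({r.compound_id for r in study.compound_targets})} compounds")
print(f"PPI edges (pre-filter)  : {len(study.ppi_edges)}")
print(f"disease sources         : {[len(s) for s in study.disease_sources]} records")
print(f"true disease union      : {len(study.truth.disease_union)} genes")
print(f"planted PPI modules     : {[len(m) for m in study.truth.planted_modules]}")
print(f"true shared targets     : {sorted(study.truth.shared_targets)[:5]} ...")
print(f"files written under     : {outdir}")
# The planted modules and shared targets are the ground truth the analysis
# stages are expected to rediscover.
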