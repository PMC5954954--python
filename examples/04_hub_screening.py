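"""Median-threshold hub screening on a PPI network.

Degree, betweenness and closeness are computed for every node; a node is a
hub when all three strictly exceed the network-wide medians (multipliers
let you demand, say, twice the median degree).
"""

from netpharm import (
    compute_centralities,
    expand_with_interactors,
    generate_study,
    screen_by_median,
)

study = generate_study(seed=1)
high_conf = [e for e in study.ppi_edges if e.score > 0.7]
net = expand_with_interactors(study.truth.disease_union, high_conf, min_seed_links=2)

table = compute_centralities(net, closeness_convention="normalized")
print("medians:", {m: round(v, 5) for m, v in table.medians.items()})

hubs = screen_by_median(table, multipliers=1.0, strict=True)
print(f"{len(hubs)} hubs out of {len(table.table)} nodes "
      f"(all three centralities above their medians):")
for h in hubs[:8]:
    row = table.table.loc[h]
    print(f"  {h}: degree={int(row.degree)} betweenness={row.betweenness:.4f} "
          f"closeness={row.closeness:.3f}")

stricter = screen_by_median(table, multipliers={"degree": 2.0}, strict=True)
print(f"with degree > 2x median: {len(stricter)} hubs (never more than before)")
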