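"""Build the four analysis networks and print their composition.

(1) the bipartite compound–target network; (2) the PPI expansion around the
compound targets; (3) the same around the disease targets; (4) their
intersection — the interactome shared by the herb's targets and the
disease's targets.  Each node carries a role: compound, compound target,
disease target, shared (compound ∩ disease) target, or other interactor.
"""

from netpharm import (
    build_bipartite_network,
    expand_with_interactors,
    generate_study,
    intersect_networks,
    summarize_network,
)

study = generate_study(seed=1)
high_conf = [e for e in study.ppi_edges if e.score > 0.7]
disease_genes = study.truth.disease_union
compound_targets = sorted({r.target for r in study.compound_targets})

bipartite = build_bipartite_network(study.compound_targets, disease_genes)
compound_net = expand_with_interactors(
    compound_targets, high_conf, min_seed_links=2,
    compound_targets=compound_targets, disease_targets=disease_genes)
disease_net = expand_with_interactors(
    disease_genes, high_conf, min_seed_links=2,
    compound_targets=compound_targets, disease_targets=disease_genes)
intersection = intersect_networks(compound_net, disease_net)

for name, net in [("compound-target (bipartite)", bipartite),
                  ("compound-target PPI", compound_net),
                  ("disease-target PPI", disease_net),
                  ("intersection", intersection)]:
    s = summarize_network(net)
    roles = ", ".join(f"{c} {r}" for r, c in sorted(s["role_counts"].items()))
    print(f"{name}: {s['n_nodes']} nodes ({roles}), {s['n_edges']} edges")
# Role counts always sum to the node total — the bookkeeping every network
# figure legend prints.
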