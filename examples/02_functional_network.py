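"""From associations to a thresholded lncRNA functional network.

Simulates a clustered lncRNA-disease association table, computes the
best-match-average functional similarity under semantic model 1, and keeps
every lncRNA pair at similarity >= 0.3 as a network edge.
"""

from lncsim import (
    SimConfig,
    build_network,
    functional_similarity_matrix,
    similarity_matrix,
    simulate_associations,
    simulate_ontology,
)

cfg = SimConfig(n_lncrna=20, seed=42)
ontology = simulate_ontology(cfg)
assoc = simulate_associations(ontology, cfg)

ss = similarity_matrix(ontology, assoc.disease_ids, model=1)
fs = functional_similarity_matrix(assoc, ss)
net = build_network(fs, cutoff=0.3)

print(f"{len(net.nodes)} lncRNAs, {len(net.edges)} edges at cutoff {net.cutoff}")
degrees = sorted(((net.degree(n), n) for n in net.nodes), reverse=True)
for deg, node in degrees[:5]:
    print(f"  {node}: degree {deg} (cluster {assoc.cluster_of[node]})")
print(
    "\nHighly connected lncRNAs share disease groups with many others; with"
    " clustered simulations the hubs sit inside the planted clusters."
)
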