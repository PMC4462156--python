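"""Leave-one-out cross-validation of the association predictor.

Each known association is withheld in turn; kernels and the withheld
lncRNA's disease group are rebuilt without it, and the pair's score is
ranked against all unknown pairs.  AUC 1.0 means every withheld pair
outranks every candidate; 0.5 is chance.
"""

from lncsim import PipelineConfig, SimConfig, loocv, simulate_associations, simulate_ontology

cfg = SimConfig(n_lncrna=24, n_clusters=4, noise_rate=0.02, seed=3)
ontology = simulate_ontology(cfg)
assoc = simulate_associations(ontology, cfg)
print(f"{assoc.n_known} known associations over "
      f"{len(assoc.lncrna_ids)} lncRNAs x {len(assoc.disease_ids)} diseases\n")

for label, config in [
    ("semantic model 1", PipelineConfig(model=1)),
    ("semantic model 2", PipelineConfig(model=2)),
    ("kernel only", PipelineConfig(model=None)),
]:
    result = loocv(assoc, ontology, config)
    print(f"{label:>18}: AUC = {result.auc:.4f} over {len(result.folds)} folds")

print(
    "\nThe semantic configurations blend ontology-derived disease and"
    " functional similarity into the kernels; at low noise all variants"
    " recover the planted cluster structure almost perfectly."
)
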