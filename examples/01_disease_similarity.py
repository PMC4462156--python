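"""Disease semantic similarity on a tiny hand-checkable hierarchy.

The vocabulary is R -> {A, B}, A -> C, encoded through tree numbers.
Model 1 weights shared ancestors by a per-layer decay factor (0.5 here);
model 2 weights them by how rare each term is across the studied DAGs.
"""

from lncsim import DiseaseOntology, similarity_matrix

ontology = DiseaseOntology(
    [
        ("R", "root disease", ["C01"]),
        ("A", "disease a", ["C01.1"]),
        ("B", "disease b", ["C01.2"]),
        ("C", "disease c", ["C01.1.1"]),
    ]
)
ids = ["R", "A", "B", "C"]

ss1 = similarity_matrix(ontology, ids, model=1, delta=0.5)
ss2 = similarity_matrix(ontology, ids, model=2)

print("model 1 (decay factor 0.5):")
print(ss1.to_frame().round(4), "\n")
print("model 2 (DAG-frequency weights):")
print(ss2.to_frame().round(4))
print(
    "\nSS1(C, A) = 2.25/3.25 =", round(ss1.loc("C", "A"), 4),
    "- C shares its ancestors A and R with A's own DAG.",
)
print(
    "SS2(C, A) =", round(ss2.loc("C", "A"), 4),
    "- the shared root R appears in every DAG and contributes nothing.",
)
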