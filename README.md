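# lncsim

Inferring what a long non-coding RNA (lncRNA) does is hard: few lncRNAs have
experimentally characterized functions, but many have curated disease
associations. `lncsim` builds on the assumption that **functionally similar
lncRNAs tend to be associated with similar diseases**: it quantifies disease
similarity from a hierarchical disease vocabulary, lifts it to a pairwise
lncRNA functional similarity, and uses the result to score unobserved
lncRNA–disease associations. It is aimed at computational biologists studying
lncRNA function and disease-gene prioritization.

## The models

**Disease semantic similarity.** Each disease `A` in a MeSH-Category-C-style
vocabulary has one or more dot-delimited tree numbers whose prefixes identify
its ancestors, giving a directed acyclic graph `DAG(A)`. Each term
`t ∈ DAG(A)` receives a contribution to the semantic value of `A`:

- *model 1 (decay):* `D_A(A) = 1`, `D_A(t) = max{Δ · D_A(t′) : t′ child of t}`
  with decay factor `0 < Δ ≤ 1` (default 0.5);
- *model 2 (DAG frequency):* `C_A(t) = −log(count(t) / N)`, where `count(t)`
  is the number of studied diseases whose DAG contains `t`.

Either way `DV(A) = Σ_t contrib_A(t)` and

```
SS(A,B) = Σ_{t ∈ D(A) ∩ D(B)} (contrib_A(t) + contrib_B(t)) / (DV(A) + DV(B))
```

**lncRNA functional similarity (best-match average).** With disease groups
`D(u)`, `D(v)` of two lncRNAs and `S(d, G) = max_{d′∈G} SS(d, d′)`:

```
FS(u,v) = [ Σ_{d∈D(u)} S(d, D(v)) + Σ_{d∈D(v)} S(d, D(u)) ] / (|D(u)| + |D(v)|)
```

**Prediction.** Functional similarity is averaged with a Gaussian
interaction-profile kernel `K(i,j) = exp(−γ‖IP(i) − IP(j)‖²)` (and optionally
Spearman expression similarity); disease similarity is averaged with the
disease-side kernel. Laplacian-regularized least squares then scores every
pair in both spaces, `F = K (K + η L K)⁻¹ Y`, and blends them with weight `w`.
Evaluation is leave-one-out cross-validation: each known association is
withheld, association-derived quantities are rebuilt without it, and its rank
among all unknown pairs yields an exact (Mann–Whitney) ROC/AUC.

## Worked example

```python
from lncsim import DiseaseOntology, similarity_matrix

ontology = DiseaseOntology([
    ("R", "root disease", ["C01"]),
    ("A", "disease a",    ["C01.1"]),
    ("B", "disease b",    ["C01.2"]),
    ("C", "disease c",    ["C01.1.1"]),
])
ss1 = similarity_matrix(ontology, ["R", "A", "B", "C"], model=1, delta=0.5)
print(round(ss1.loc("C", "A"), 4))   # 0.6923
```

`SS1(C, A) = 2.25/3.25 ≈ 0.6923`: C's DAG contributes `{C:1, A:0.5, R:0.25}`,
A's contributes `{A:1, R:0.5}`, and the shared terms A and R carry
`(0.5+1) + (0.25+0.5) = 2.25` of the total `1.75 + 1.5 = 3.25`. Under model 2
the same pair scores exactly 0.5, because the root R sits in every DAG and
carries zero weight. The scripts in `examples/` walk through each capability
(similarity matrices, the thresholded functional network, candidate ranking,
cross-validation) and print annotated output; `examples/04_loocv.py` reports,
for a 24-lncRNA simulation at 2% noise, LOOCV AUCs of 0.8997 (model 1),
0.9144 (model 2) and 0.8888 (kernels only).

There is also a CLI mirroring the library
(`lncsim simulate | disease-sim | lncrna-sim | network | predict | loocv`),
each stage writing TSV outputs plus a manifest with parameters, seed and
input checksums.

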