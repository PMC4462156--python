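# Methods

## Vocabulary and per-disease DAGs

A disease vocabulary assigns each term one or more dot-delimited tree
numbers. The parent of a code is its longest proper prefix that resolves to
a known term; prefixes absent from the vocabulary are skipped (logged), so a
partial vocabulary still yields connected ancestry instead of aborting a
run. A term with several codes therefore has several parents, and the
derived relation is validated to be acyclic.

`DAG(A)` contains `A` plus every term owning a proper prefix of any of `A`'s
codes — the union over codes, weighting all trees equally — with every
parent→child pair among those terms as edges. Layers are shortest directed
path lengths down to `A` (breadth-first search over reversed edges), used
for reporting; model-1 contributions are computed by the recursion itself,
not from layers. Every DAG node provably reaches `A` along prefix-owner
chains, so the recursion is total; a disconnected node (possible only with
pathological partial vocabularies) falls back to the layer closed form.

## Semantic similarity

Model 1 uses max-over-children decay: `D_A(A)=1`,
`D_A(t) = max{Δ·D_A(t′)}` over children `t′` of `t` inside the DAG. On trees
this reduces to `Δ^layer`; on diamond-shaped DAGs the max makes the shortest
path dominate. Default `Δ = 0.5`, exposed everywhere; similarity is the
shared-contribution ratio given in the README and is *not* monotone in `Δ`
in general (an ancestor/descendant pair gives `(1+Δ²)/(2+Δ+Δ²)`, which dips
near `Δ→1`), which is why the test suite checks Δ-dependence only on a
corpus where monotonicity provably holds.

Model 2 replaces (not augments) the decay with rarity weights
`−log(count(t)/N)` counted over the *studied* diseases (the association
table's columns), not the whole vocabulary; a narrower explicit corpus can
be supplied, in which case unseen terms count once (their own DAG). The
natural log is the default; similarity is provably log-base invariant
(verified against bases 2 and 10), semantic values are not. Two distinct
diseases whose DAGs contain only universally shared terms have zero
semantic value on both sides; their similarity is defined as 0 to avoid
0/0. Self-similarity is pinned to exactly 1 in both models, bypassing
floating-point summation.

## Functional similarity and network

Best-match average over disease groups, as in the README. lncRNAs with no
associated diseases cannot be scored and are excluded (logged) rather than
given zero rows — zeros would systematically depress them in the downstream
average; the Gaussian kernel still covers them. The functional network
connects pairs with similarity ≥ cutoff (default 0.3, chosen low because
curated association sets are sparse and incomplete); isolated nodes are
kept by default since node degree is a reported quantity. Exports: SIF and
weighted edge-list TSV.

## Kernels and integration

Gaussian interaction-profile kernel with bandwidth
`γ = γ′ / mean‖IP‖²` and `γ′ = 1` by default on both axes (configurable);
an all-zero association matrix leaves `γ` undefined and returns the
identity with a warning. Expression similarity is the Spearman correlation
mapped to `[0,1]` by `(r+1)/2` so that all averaged sources share one
scale; `|r|` is available behind a flag for sign-agnostic co-expression.
Constant profiles have undefined correlation, treated as `r = 0` (logged).

Disease-side integration is the plain mean of semantic similarity and the
disease kernel. lncRNA-side integration averages, per pair, whichever of
{kernel, functional, expression} are defined for that pair — the kernel
always is — instead of imputing zeros for missing sources. Expression input
is optional everywhere; the headline cross-validation configuration runs
without it.

## Laplacian-regularized least squares

Normalized Laplacian `L = I − D^(−1/2) S D^(−1/2)` (zero-degree rows become
identity rows; combinatorial form behind a flag). The solver returns the
representer minimizer `F = K (K + ηLK + jitter·I)⁻¹ Y`; with invertible `K`
this equals the unconstrained minimizer `(I + ηL)⁻¹Y` of
`‖Y−F‖² + η·tr(FᵀLF)`, which is what the test oracle minimizes
numerically. `η = 0` short-circuits to `F = Y` (the exact interpolation
limit). Defaults `η_l = η_d = 1`, blend weight `w = 0.5`, jitter `1e-8`;
all configurable, and chosen as neutral conventions rather than tuned
values. Known associations are not masked in the score matrix: the ranker
filters known pairs, and cross-validation needs the withheld pair's score.
Ranking breaks ties by stable identifier order and supports per-disease and
global scopes.

## Cross-validation and ROC

Each known association is withheld in turn. Per fold, both Gaussian kernels
are recomputed from the reduced matrix and the withheld lncRNA's disease
group is shrunk before its functional-similarity row is recomputed (an
lncRNA losing its only disease drops out of the functional source entirely
for that fold). Both leak-avoidance steps can be disabled for sensitivity
analysis; a test asserts the leaky variant never looks worse, the expected
direction of leakage. Semantic similarity is ontology-derived and stays
fixed across folds. Candidates default to *all* unknown pairs (per-disease
scope optional).

The withheld pair receives the midrank of its tie group among itself plus
the candidates. The reported AUC is the Mann–Whitney concordance
`Σ(n+1−rank) / Σn`, exact under ties. The ROC curve is swept over every
integer cutoff and every achieved midrank using positional negative counts;
for untied ranks at a constant candidate count — the global-scope situation
— its trapezoidal area equals the reported AUC to machine precision, while
under heavy ties or mixed per-disease fold sizes the curve is a plotting
aid and the concordance form remains the definition. A constant scorer
yields exactly 0.5.

## Synthetic data

The generators emulate what the functional-similarity assumption needs: a
complete b-ary tree vocabulary (`C`, `C.1`, …; depth 3, branching 3 → 40
terms by default); lncRNAs assigned round-robin to clusters, each cluster
drawing its planted diseases from one disjoint subtree (the shallowest
level with enough subtrees); symmetric per-cell bit-flip noise (default
0.05) producing both spurious and missing associations; and cluster-mean
expression profiles (standard-normal means, noise SD 0.5, 20 samples).
Defaults of 40 lncRNAs, 4 clusters and 3 associations per lncRNA reflect
the sparsity of curated association sets (a few associations per lncRNA).
Each generator draws from one explicitly seeded stream
(`default_rng([seed, tag])`), so all outputs are byte-reproducible from
(config, seed).

What the simulations do *not* emulate: scale-free association degree
distributions, disease-specific annotation bias, correlated (non-uniform)
noise, and multi-tree disease descriptors. Passing recovery tests therefore
demonstrates that the pipeline recovers planted block structure through the
full similarity→solver→ranking path, not that real-data accuracy reaches
any particular level.

A consequence of the per-cell noise model worth knowing: at the default
0.05 rate on a 40×40 matrix, roughly a third of all *known* associations
are noise-planted random pairs. Each becomes a cross-validation fold whose
concordance hovers near 0.5 no matter the scorer, capping the attainable
LOOCV AUC near 0.8 at these dimensions (measured ≈ 0.73–0.78 across seeds
and configurations; the noise-free limit is ≈ 0.98). At lower noise the
semantic configurations beat the kernel-only one (e.g. 0.90/0.91 vs 0.89 at
2% noise in `examples/04_loocv.py`); at 5% the model-2 variant still does,
while the flatter model-1 similarity can slightly dilute an already strong
kernel.

## Known limitations

- Functional similarity is biased toward lncRNAs with many associated
  diseases; group size enters only through the denominator.
- The decay factor Δ has no principled selection rule; 0.5 is convention.
- The solver's linear blend of the two space solutions (weight `w`) is a
  declared design choice; alternatives (e.g. geometric combination) are not
  implemented.
- No synonym resolution or native vocabulary-file parsing: inputs are plain
  TSV tables (descriptor table, association list, optional name map).
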