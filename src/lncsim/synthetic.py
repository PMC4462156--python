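"""Synthetic ontologies, association tables, and expression profiles.

The generators emulate the structure the functional-similarity assumption
relies on: a rooted multi-level disease hierarchy, lncRNAs organized in
functional clusters whose associated diseases come from one subtree each
(so that functionally related lncRNAs share semantically related diseases),
symmetric bit-flip noise on the association matrix (producing both spurious
and missing associations), and expression profiles correlated within
clusters.  Every generator draws from a single explicitly seeded stream and
is byte-reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import AssociationTable
from .exceptions import ParameterError, ValidationError
from .ontology import DiseaseOntology

ROOT_CODE = "C"


@dataclasses.dataclass
class SimConfig:
    """Generator settings.

    depth, branching:
        the vocabulary is a complete ``branching``-ary tree with ``depth``
        levels below the root (``(b**(d+1) - 1) / (b - 1)`` terms).
    n_lncrna, n_clusters:
        lncRNAs are assigned round-robin to clusters; each cluster owns one
        disjoint subtree of the hierarchy.
    assoc_per_lncrna:
        planted associations per lncRNA, drawn without replacement from the
        cluster's subtree (capped at the subtree size).
    noise_rate:
        per-cell probability of flipping an association bit.
    n_samples, expression_noise:
        expression profiles are cluster means (standard normal) plus
        independent normal noise of this standard deviation.
    """

    depth: int = 3
    branching: int = 3
    n_lncrna: int = 40
    n_clusters: int = 4
    assoc_per_lncrna: int = 3
    noise_rate: float = 0.05
    n_samples: int = 20
    expression_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.branching < 1:
            raise ParameterError("depth and branching must be >= 1")
        if self.n_lncrna < 1 or self.n_clusters < 1 or self.assoc_per_lncrna < 1:
            raise ParameterError("n_lncrna, n_clusters, assoc_per_lncrna must be >= 1")
        if not (0 <= self.noise_rate <= 1):
            raise ParameterError("noise_rate must be in [0, 1]")
        if self.n_samples < 3:
            raise ParameterError("expression profiles need >= 3 samples")


def _tree_codes(depth: int, branching: int) -> list[str]:
    codes = [ROOT_CODE]
    frontier = [ROOT_CODE]
    for _ in range(depth):
        frontier = [f"{p}.{k}" for p in frontier for k in range(1, branching + 1)]
        codes.extend(frontier)
    return codes


def simulate_ontology(cfg: SimConfig) -> DiseaseOntology:
    """Complete b-ary tree vocabulary with codes ``C``, ``C.1``, ``C.1.2``, ...

    Term ids equal the tree-number codes; fully deterministic.
    """
    return DiseaseOntology(
        (code, f"disease {code}", [code]) for code in _tree_codes(cfg.depth, cfg.branching)
    )


def _cluster_pools(cfg: SimConfig) -> list[list[str]]:
    """One disjoint subtree (root + descendants) per cluster."""
    level = 1
    while cfg.branching ** level < cfg.n_clusters:
        level += 1
    if level > cfg.depth:
        raise ParameterError(
            f"{cfg.n_clusters} clusters need {cfg.n_clusters} disjoint subtrees; the "
            f"hierarchy (depth {cfg.depth}, branching {cfg.branching}) has at most "
            f"{cfg.branching ** cfg.depth}"
        )
    all_codes = _tree_codes(cfg.depth, cfg.branching)
    roots = [c for c in all_codes if c.count(".") == level][: cfg.n_clusters]
    return [[c for c in all_codes if c == r or c.startswith(r + ".")] for r in roots]


def simulate_associations(ontology: DiseaseOntology, cfg: SimConfig) -> AssociationTable:
    """Clustered binary association matrix over the full vocabulary.

    lncRNA ``k`` belongs to cluster ``k mod n_clusters`` and its planted
    diseases are drawn from that cluster's subtree; every cell is then
    flipped with probability ``noise_rate``.  Cluster labels are attached to
    the returned table as ``cluster_of``.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    pools = _cluster_pools(cfg)
    disease_ids = sorted(ontology.term_ids())
    di = {d: k for k, d in enumerate(disease_ids)}
    width = len(str(cfg.n_lncrna))
    lncrna_ids = [f"L{k + 1:0{width}d}" for k in range(cfg.n_lncrna)]
    clusters = {l: k % cfg.n_clusters for k, l in enumerate(lncrna_ids)}
    m = np.zeros((cfg.n_lncrna, len(disease_ids)), dtype=np.int8)
    for k, lnc in enumerate(lncrna_ids):
        pool = pools[clusters[lnc]]
        take = min(cfg.assoc_per_lncrna, len(pool))
        for d in rng.choice(pool, size=take, replace=False):
            m[k, di[d]] = 1
    if cfg.noise_rate > 0:
        flips = rng.random(m.shape) < cfg.noise_rate
        m = np.where(flips, 1 - m, m).astype(np.int8)
    return AssociationTable(lncrna_ids, disease_ids, m, cluster_of=clusters)


def simulate_expression(
    assoc: AssociationTable, cfg: SimConfig, clusters: dict[str, int] | None = None
) -> pd.DataFrame:
    """Cluster-mean expression profiles plus independent noise.

    Rows follow the association table's lncRNA order; columns are sample
    ids.  Within-cluster profiles share a mean vector, so their rank
    correlation exceeds the between-cluster one on average.
    """
    clusters = clusters if clusters is not None else assoc.cluster_of
    if clusters is None:
        raise ValidationError(
            "cluster labels required: pass clusters= or use a simulated table"
        )
    rng = np.random.default_rng([cfg.seed, 2])
    n_clusters = max(clusters.values()) + 1
    means = rng.standard_normal((n_clusters, cfg.n_samples))
    rows = np.empty((len(assoc.lncrna_ids), cfg.n_samples))
    for k, lnc in enumerate(assoc.lncrna_ids):
        rows[k] = means[clusters[lnc]] + cfg.expression_noise * rng.standard_normal(
            cfg.n_samples
        )
    return pd.DataFrame(
        rows,
        index=assoc.lncrna_ids,
        columns=[f"S{j + 1}" for j in range(cfg.n_samples)],
    )


def write_simulated_inputs(cfg: SimConfig, out_dir) -> dict[str, str]:
    """Generate and write the three TSV inputs consumed by the CLI stages."""
    import os

    ontology = simulate_ontology(cfg)
    assoc = simulate_associations(ontology, cfg)
    expr = simulate_expression(assoc, cfg)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ontology": os.path.join(out_dir, "ontology.tsv"),
        "associations": os.path.join(out_dir, "associations.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
    }
    with open(paths["ontology"], "w") as fh:
        fh.write("term_id\tname\ttree_numbers\n")
        for tid in ontology.term_ids():
            t = ontology.terms[tid]
            fh.write(f"{t.term_id}\t{t.name}\t{';'.join(sorted(t.tree_numbers))}\n")
    assoc.to_tsv(paths["associations"])
    expr.to_csv(paths["expression"], sep="\t", index_label="lncrna", float_format="%.10g")
    return paths
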