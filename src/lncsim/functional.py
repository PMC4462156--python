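"""Best-match-average lncRNA functional similarity (the LNCSIM statistic).

Functionally similar lncRNAs tend to be associated with similar diseases, so
the similarity of two lncRNAs ``u`` and ``v`` is measured on their disease
groups ``D(u)`` and ``D(v)``: every disease takes its best match in the other
group under a disease semantic-similarity matrix ``SS`` and the matches are
averaged over both groups::

    S(d, G)  = max_{d' in G} SS(d, d')
    FS(u, v) = [ sum_{d in D(u)} S(d, D(v)) + sum_{d in D(v)} S(d, D(u)) ]
               / (|D(u)| + |D(v)|)

lncRNAs without any associated disease cannot be scored this way and are
excluded from the matrix (logged); the Gaussian profile kernel in
:mod:`lncsim.kernels` still covers them downstream.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Set

import networkx as nx
import numpy as np

from .containers import AssociationTable, SimilarityMatrix
from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.3


def disease_groups(assoc: AssociationTable) -> dict[str, set[str]]:
    """``D(u)`` for every lncRNA: the diseases it is associated with."""
    out: dict[str, set[str]] = {}
    for i, lnc in enumerate(assoc.lncrna_ids):
        cols = np.flatnonzero(assoc.matrix[i])
        out[lnc] = {assoc.disease_ids[j] for j in cols}
    return out


def group_similarity(d: str, group: Set[str], ss: SimilarityMatrix) -> float:
    """Best match of disease ``d`` against a disease group."""
    if not group:
        raise ValidationError("disease group is empty")
    i = ss.index_of(d)
    idx = [ss.index_of(g) for g in group]
    return float(ss.values[i, idx].max())


def functional_similarity(gu: Set[str], gv: Set[str], ss: SimilarityMatrix) -> float:
    """Best-match-average similarity of two disease groups."""
    if not gu or not gv:
        raise ValidationError("disease groups must be non-empty")
    iu = [ss.index_of(d) for d in gu]
    iv = [ss.index_of(d) for d in gv]
    block = ss.values[np.ix_(iu, iv)]
    total = block.max(axis=1).sum() + block.max(axis=0).sum()
    return float(total / (len(iu) + len(iv)))


def functional_similarity_matrix(
    assoc: AssociationTable, ss: SimilarityMatrix
) -> SimilarityMatrix:
    """Pairwise functional similarity over all lncRNAs with >= 1 disease."""
    groups = disease_groups(assoc)
    included = [l for l in assoc.lncrna_ids if groups[l]]
    excluded = [l for l in assoc.lncrna_ids if not groups[l]]
    if excluded:
        logger.info(
            "excluding %d lncRNAs without associated diseases: %s%s",
            len(excluded), excluded[:5], "..." if len(excluded) > 5 else "",
        )
    if not included:
        raise ValidationError("no lncRNA has any associated disease")
    idx = {l: sorted(ss.index_of(d) for d in groups[l]) for l in included}
    n = len(included)
    m = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            block = ss.values[np.ix_(idx[included[a]], idx[included[b]])]
            m[a, b] = m[b, a] = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (
                block.shape[0] + block.shape[1]
            )
    return SimilarityMatrix(included, m).validate()


def combine_functional_similarities(
    fs1: SimilarityMatrix, fs2: SimilarityMatrix, mode: str = "mean"
) -> SimilarityMatrix:
    """Element-wise mean/max/min of the two model variants."""
    if fs1.ids != fs2.ids:
        raise ValidationError("functional similarity matrices index different lncRNAs")
    ops = {"mean": lambda a, b: (a + b) / 2, "max": np.maximum, "min": np.minimum}
    if mode not in ops:
        raise ParameterError(f"mode must be one of {sorted(ops)}, got {mode!r}")
    out = SimilarityMatrix(list(fs1.ids), ops[mode](fs1.values, fs2.values))
    np.fill_diagonal(out.values, 1.0)
    return out.validate()


@dataclasses.dataclass
class FunctionalNetwork:
    """Thresholded functional-similarity network (undirected, weighted)."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, _ in self.edges:
                fh.write(f"{u}\tsim\t{v}\n")

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id1\tid2\tweight\n")
            for u, v, w in self.edges:
                fh.write(f"{u}\t{v}\t{w:.10g}\n")


def build_network(
    fs: SimilarityMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    include_isolated: bool = True,
) -> FunctionalNetwork:
    """Connect lncRNA pairs whose functional similarity is >= ``cutoff``.

    Isolated nodes are kept by default (node degree is a quantity of
    interest); pass ``include_isolated=False`` to drop them.
    """
    if not (0 <= cutoff):
        raise ParameterError(f"cutoff must be non-negative, got {cutoff}")
    g = nx.Graph()
    if include_isolated:
        g.add_nodes_from(fs.ids)
    n = len(fs.ids)
    for a in range(n):
        for b in range(a + 1, n):
            w = fs.values[a, b]
            if w >= cutoff:
                g.add_edge(fs.ids[a], fs.ids[b], weight=float(w))
    return FunctionalNetwork(g, cutoff)
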