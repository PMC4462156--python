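"""Auxiliary similarities: Gaussian interaction-profile kernels, expression
similarity, and the integration rules that merge them with the semantic and
functional similarities.

The interaction profile ``IP(e)`` of an entity is its binary row (lncRNA) or
column (disease) of the association matrix; the kernel is

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2),
    gamma   = gamma_prime / mean_e ||IP(e)||^2

so the bandwidth adapts to the average profile density.  Expression
similarity is the Spearman rank correlation of two expression profiles,
rescaled to [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy.stats import rankdata

from .containers import AssociationTable, SimilarityMatrix
from .exceptions import ParameterError, ValidationError

logger = logging.getLogger(__name__)


def gaussian_profile_kernel(
    assoc: AssociationTable, axis: str = "lncrna", gamma_prime: float = 1.0
) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over one axis of the association matrix.

    With an empty association matrix the bandwidth is undefined; the identity
    matrix is returned with a warning.
    """
    if gamma_prime <= 0:
        raise ParameterError(f"gamma_prime must be positive, got {gamma_prime}")
    if axis == "lncrna":
        profiles, ids = assoc.matrix.astype(float), assoc.lncrna_ids
    elif axis == "disease":
        profiles, ids = assoc.matrix.T.astype(float), assoc.disease_ids
    else:
        raise ParameterError(f"axis must be 'lncrna' or 'disease', got {axis!r}")
    mean_sq = (profiles ** 2).sum(axis=1).mean()
    if mean_sq == 0:
        logger.warning("all interaction profiles are empty; returning identity kernel")
        return SimilarityMatrix(list(ids), np.eye(len(ids)))
    gamma = gamma_prime / mean_sq
    d2 = squareform(pdist(profiles, metric="sqeuclidean"))
    k = np.exp(-gamma * d2)
    np.fill_diagonal(k, 1.0)
    return SimilarityMatrix(list(ids), k).validate()


def expression_similarity(expr: pd.DataFrame, mode: str = "shifted") -> SimilarityMatrix:
    """Rank-correlation similarity of lncRNA expression profiles.

    ``expr`` has lncRNAs as rows and samples as columns (>= 3 samples).
    ``mode='shifted'`` maps the Spearman coefficient via ``(r + 1) / 2``;
    ``mode='absolute'`` uses ``|r|``.  Constant profiles have undefined
    correlation: it is treated as 0 (logged), i.e. similarity 0.5 under the
    shifted map.
    """
    if mode not in ("shifted", "absolute"):
        raise ParameterError(f"mode must be 'shifted' or 'absolute', got {mode!r}")
    if expr.shape[1] < 3:
        raise ValidationError("expression profiles need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, x)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant expression profiles; their correlations treated as 0",
            int(constant.sum()),
        )
        sd = np.where(constant, 1.0, sd)
    centered = (ranks - ranks.mean(axis=1, keepdims=True)) / sd[:, None]
    r = centered @ centered.T / x.shape[1]
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    r = np.clip(r, -1.0, 1.0)
    sim = (r + 1.0) / 2.0 if mode == "shifted" else np.abs(r)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(list(expr.index.astype(str)), sim).validate()


def integrate_disease_similarity(
    ss: SimilarityMatrix, kd: SimilarityMatrix
) -> SimilarityMatrix:
    """Simple mean of semantic similarity and the disease profile kernel."""
    if ss.ids != kd.ids:
        raise ValidationError("disease similarity matrices index different diseases")
    return SimilarityMatrix(list(ss.ids), (ss.values + kd.values) / 2.0).validate()


def integrate_lncrna_similarity(
    kl: SimilarityMatrix,
    fs: SimilarityMatrix | None = None,
    es: SimilarityMatrix | None = None,
) -> SimilarityMatrix:
    """Average of the lncRNA similarity sources available for each pair.

    The profile kernel ``kl`` defines the index and covers every pair; the
    functional similarity ``fs`` may cover only the lncRNAs with associated
    diseases and the expression similarity ``es`` only the profiled ones.
    Each pair is averaged over the sources defined for it rather than
    imputing zeros for the missing ones.
    """
    ids = list(kl.ids)
    total = kl.values.copy()
    count = np.ones_like(total)
    for src in (fs, es):
        if src is None:
            continue
        extra = sorted(set(src.ids) - set(ids))
        if extra:
            raise ValidationError(f"similarity source covers unknown lncRNAs: {extra[:5]}")
        pos = np.array([ids.index(i) for i in src.ids])
        total[np.ix_(pos, pos)] += src.values
        count[np.ix_(pos, pos)] += 1.0
    out = total / count
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(ids, out).validate()
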