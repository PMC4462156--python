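"""Laplacian-regularized least-squares association scoring.

Given a similarity (kernel) matrix ``K`` over entities and targets ``Y``,
the score matrix ``F = K alpha`` minimizes

    ||Y - F||_F^2  +  eta * trace(F^T L F)

over the kernel representer, where ``L`` is the (normalized) graph Laplacian
of the similarity network.  The closed-form solution is

    F = K (K + eta * L * K + jitter * I)^(-1) Y .

Scoring runs once in the lncRNA similarity space on the association matrix
``A`` and once in the disease space on ``A^T``; the two score matrices are
blended linearly with weight ``w``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .containers import AssociationTable, ScoreMatrix, SimilarityMatrix
from .exceptions import NumericalError, ParameterError, ValidationError


@dataclasses.dataclass
class LRLSParams:
    """Solver hyper-parameters.

    eta_l, eta_d:
        regularization strengths in the lncRNA and disease spaces (>= 0;
        0 turns the solver into pure interpolation).
    w:
        weight of the lncRNA-space solution in the final blend, in [0, 1].
    jitter:
        small diagonal shift applied before inversion for conditioning.
    """

    eta_l: float = 1.0
    eta_d: float = 1.0
    w: float = 0.5
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if self.eta_l < 0 or self.eta_d < 0:
            raise ParameterError("regularization strengths must be non-negative")
        if not (0 <= self.w <= 1):
            raise ParameterError(f"combination weight must be in [0, 1], got {self.w}")
        if self.jitter < 0:
            raise ParameterError("jitter must be non-negative")


def normalized_laplacian(s: SimilarityMatrix | np.ndarray, normalized: bool = True) -> np.ndarray:
    """Graph Laplacian of a symmetric non-negative similarity matrix.

    Normalized form ``L = I - D^(-1/2) S D^(-1/2)``; rows with zero degree
    get the corresponding identity row.  ``normalized=False`` gives the
    combinatorial form ``D - S``.
    """
    v = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValidationError("Laplacian input must be square")
    if not np.allclose(v, v.T, atol=1e-8):
        raise ValidationError("Laplacian input must be symmetric")
    if v.min() < 0:
        raise ValidationError("Laplacian input must be non-negative")
    deg = v.sum(axis=1)
    if not normalized:
        return np.diag(deg) - v
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = np.eye(len(deg)) - inv_sqrt[:, None] * v * inv_sqrt[None, :]
    zero = deg == 0
    if zero.any():
        lap[zero, :] = 0.0
        lap[:, zero] = 0.0
        lap[zero, zero] = 1.0
    return (lap + lap.T) / 2.0


def lrls_solve(
    K: np.ndarray | SimilarityMatrix,
    L: np.ndarray,
    Y: np.ndarray,
    eta: float,
    jitter: float = 1e-8,
) -> np.ndarray:
    """Closed-form Laplacian-RLS solution ``K (K + eta L K + jitter I)^-1 Y``.

    ``eta = 0`` is the interpolation limit and returns ``Y`` directly (exact
    for any invertible kernel).  A singular system that the jitter cannot
    rescue raises :class:`NumericalError` advising a larger jitter.
    """
    K = K.values if isinstance(K, SimilarityMatrix) else np.asarray(K, dtype=float)
    L = np.asarray(L, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if eta < 0:
        raise ParameterError(f"eta must be non-negative, got {eta}")
    if K.shape != L.shape or K.shape[0] != Y.shape[0]:
        raise ValidationError("K, L, Y shapes are inconsistent")
    if eta == 0:
        return Y.astype(float).copy()
    system = K + eta * (L @ K) + jitter * np.eye(K.shape[0])
    try:
        f = K @ np.linalg.solve(system, Y)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"Laplacian-RLS system is singular ({exc}); raise the jitter"
        ) from exc
    if not np.isfinite(f).all():
        raise NumericalError("Laplacian-RLS solution is non-finite; raise the jitter")
    return f


def predict(
    assoc: AssociationTable,
    sl: SimilarityMatrix,
    sd: SimilarityMatrix,
    params: LRLSParams | None = None,
) -> ScoreMatrix:
    """Score all lncRNA-disease pairs in both similarity spaces and blend.

    Known associations keep their scores (no masking): the ranker, not the
    solver, filters known pairs, and cross-validation needs the left-out
    pair's score.
    """
    params = params or LRLSParams()
    if sl.ids != assoc.lncrna_ids or sd.ids != assoc.disease_ids:
        raise ValidationError("similarity matrices do not index the association table")
    a = assoc.matrix.astype(float)
    ll = normalized_laplacian(sl)
    ld = normalized_laplacian(sd)
    f_l = lrls_solve(sl.values, ll, a, params.eta_l, params.jitter)
    f_d = lrls_solve(sd.values, ld, a.T, params.eta_d, params.jitter).T
    scores = params.w * f_l + (1.0 - params.w) * f_d
    return ScoreMatrix(list(assoc.lncrna_ids), list(assoc.disease_ids), scores)


def rank_candidates(
    scores: ScoreMatrix,
    known: AssociationTable,
    scope: str = "per-disease",
) -> pd.DataFrame:
    """Rank unknown lncRNA-disease pairs by descending score.

    ``scope='per-disease'`` ranks the candidate lncRNAs within each disease
    column; ``scope='global'`` ranks every unknown pair jointly.  Ties break
    by the stable (lncRNA, disease) identifier order of the score matrix.
    Returns a frame with columns ``lncrna, disease, score, rank``.
    """
    if scope not in ("per-disease", "global"):
        raise ParameterError(f"scope must be 'per-disease' or 'global', got {scope!r}")
    if (
        scores.lncrna_ids != known.lncrna_ids
        or scores.disease_ids != known.disease_ids
    ):
        raise ValidationError("score and association matrices index different entities")
    rows = []
    for i, j in np.argwhere(known.matrix == 0):
        rows.append(
            (scores.lncrna_ids[i], scores.disease_ids[j], scores.scores[i, j], i, j)
        )
    df = pd.DataFrame(rows, columns=["lncrna", "disease", "score", "_i", "_j"])
    df = df.sort_values(
        ["score", "_i", "_j"], ascending=[False, True, True], kind="stable"
    )
    if scope == "global":
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df["rank"] = df.groupby("_j").cumcount() + 1
        df = df.sort_values(["_j", "rank"], kind="stable")
    return df.drop(columns=["_i", "_j"]).reset_index(drop=True)
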