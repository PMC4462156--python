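"""Shared in-memory containers: similarity matrices, association tables, scores.

These are thin, validated wrappers around numpy arrays with an identifier
index, plus TSV round-tripping.  All pipeline stages exchange data through
them, so the invariants (symmetry, unit diagonal, binary entries, unique ids)
are enforced here once instead of in every consumer.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclasses.dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over a list of identifiers.

    Entries are expected in [0, 1] with a unit diagonal; :meth:`validate`
    enforces this (construction does not, so intermediate arithmetic such as
    element-wise means can pass through).
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = _check_unique(self.ids, "similarity")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} identifiers"
            )
        self._index = {t: k for k, t in enumerate(self.ids)}

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def index_of(self, term: str) -> int:
        try:
            return self._index[term]
        except KeyError:
            raise KeyError(f"identifier {term!r} not in similarity matrix") from None

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self.index_of(i), self.index_of(j)])

    def submatrix(self, ids: Sequence[str]) -> "SimilarityMatrix":
        idx = [self.index_of(i) for i in ids]
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)].copy())

    def validate(self, atol: float = 1e-8) -> "SimilarityMatrix":
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValidationError("similarity matrix diagonal is not 1")
        if v.min() < -atol or v.max() > 1 + atol:
            raise ValidationError("similarity entries outside [0, 1]")
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.10g")

    def to_long_tsv(self, path) -> None:
        """Long-format (i, j, value) export of the upper triangle."""
        rows = []
        for a in range(len(self.ids)):
            for b in range(a, len(self.ids)):
                rows.append((self.ids[a], self.ids[b], self.values[a, b]))
        pd.DataFrame(rows, columns=["i", "j", "value"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


@dataclasses.dataclass
class AssociationTable:
    """Binary lncRNA x disease association matrix with identifier indices."""

    lncrna_ids: list[str]
    disease_ids: list[str]
    matrix: np.ndarray
    #: optional simulator metadata: lncRNA id -> cluster label
    cluster_of: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.lncrna_ids = _check_unique(self.lncrna_ids, "lncRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        m = np.asarray(self.matrix)
        if m.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValidationError(
                f"association matrix shape {m.shape} does not match "
                f"{len(self.lncrna_ids)} lncRNAs x {len(self.disease_ids)} diseases"
            )
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("association entries must be 0 or 1")
        self.matrix = m.astype(np.int8)
        self._li = {t: k for k, t in enumerate(self.lncrna_ids)}
        self._di = {t: k for k, t in enumerate(self.disease_ids)}

    @property
    def n_known(self) -> int:
        return int(self.matrix.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """(row, column) indices of known associations, row-major order."""
        return [tuple(p) for p in np.argwhere(self.matrix == 1)]

    def lncrna_index(self, lncrna: str) -> int:
        return self._li[lncrna]

    def disease_index(self, disease: str) -> int:
        return self._di[disease]

    def without(self, pair: tuple[int, int]) -> "AssociationTable":
        """Copy with one known association reset to 0 (LOOCV fold input)."""
        m = self.matrix.copy()
        if m[pair] != 1:
            raise ValidationError(f"pair {pair} is not a known association")
        m[pair] = 0
        return dataclasses.replace(self, matrix=m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.lncrna_ids, columns=self.disease_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="lncrna")

    @classmethod
    def from_tsv(cls, path) -> "AssociationTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            list(df.index.astype(str)),
            list(df.columns.astype(str)),
            df.to_numpy(),
        )


@dataclasses.dataclass
class ScoreMatrix:
    """Real-valued lncRNA x disease prediction scores."""

    lncrna_ids: list[str]
    disease_ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_ids = _check_unique(self.lncrna_ids, "lncRNA")
        self.disease_ids = _check_unique(self.disease_ids, "disease")
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.lncrna_ids), len(self.disease_ids)):
            raise ValidationError("score matrix shape does not match identifiers")
        if not np.isfinite(s).all():
            raise ValidationError("score matrix contains non-finite entries")
        self.scores = s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.lncrna_ids, columns=self.disease_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="lncrna", float_format="%.10g")
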