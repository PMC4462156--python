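"""Disease semantic similarity from per-disease DAGs.

Two models quantify how much each term ``t`` in ``DAG(A)`` contributes to the
*semantic value* of disease ``A``:

Model 1 (decay-factor):
    the disease itself contributes 1 and every step toward more general
    ancestors multiplies the contribution by a decay factor ``0 < delta <= 1``;
    when several downward paths exist the largest contribution wins::

        D_A(A) = 1
        D_A(t) = max{ delta * D_A(t') : t' a child of t within DAG(A) }

Model 2 (DAG-frequency):
    a term appearing in few diseases' DAGs is more specific and should weigh
    more, independent of its layer::

        C_A(t) = -log( count(t) / n_diseases )

    where ``count(t)`` is the number of studied diseases whose DAG contains
    ``t``.  A term present in every DAG contributes 0.

Either way the semantic value ``DV(A)`` is the sum of contributions over
``DAG(A)``, and the similarity of two diseases is the contribution mass they
share::

    SS(A, B) = sum_{t in D(A) ∩ D(B)} (contrib_A(t) + contrib_B(t))
               / (DV(A) + DV(B))

Self-similarity is fixed to exactly 1.  Model-2 similarity is invariant to
the logarithm base (the base cancels in the ratio); semantic values are not.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np

from .containers import SimilarityMatrix
from .exceptions import ParameterError, ValidationError
from .ontology import DiseaseDAG, DiseaseOntology, build_dag

DEFAULT_DELTA = 0.5


@dataclasses.dataclass
class ContributionMap:
    """Per-term contributions to one disease's semantic value."""

    disease: str
    values: dict[str, float]
    model: int


@dataclasses.dataclass
class SemanticValue:
    disease: str
    value: float
    model: int


def contribution_model1(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> ContributionMap:
    """Decay-factor contributions of every term in ``DAG(A)``."""
    if not (0 < delta <= 1):
        raise ParameterError(f"decay factor must be in (0, 1], got {delta}")
    memo: dict[str, float] = {dag.disease: 1.0}

    def contrib(t: str) -> float:
        if t in memo:
            return memo[t]
        memo[t] = -1.0  # cycle guard; DAGs are acyclic so never observed
        kids = dag.children_within(t)
        if kids:
            val = delta * max(contrib(k) for k in kids)
        else:
            # Node with no downward edge inside the DAG (partial vocabulary):
            # fall back to the layer-based closed form.
            val = delta ** dag.layer[t]
        memo[t] = val
        return val

    return ContributionMap(dag.disease, {t: contrib(t) for t in dag.nodes}, model=1)


def semantic_value(contribs: ContributionMap) -> SemanticValue:
    """Sum of all contributions in the map (``DV(A)`` / ``C2(A)``)."""
    return SemanticValue(contribs.disease, float(sum(contribs.values.values())), contribs.model)


def similarity_model1(dagA: DiseaseDAG, dagB: DiseaseDAG, delta: float = DEFAULT_DELTA) -> float:
    """Model-1 semantic similarity of two diseases (shared-contribution ratio)."""
    if dagA.disease == dagB.disease:
        return 1.0
    ca = contribution_model1(dagA, delta).values
    cb = contribution_model1(dagB, delta).values
    shared = dagA.nodes & dagB.nodes
    num = sum(ca[t] + cb[t] for t in shared)
    den = sum(ca.values()) + sum(cb.values())
    return num / den


def dag_membership_counts(corpus: Sequence[DiseaseDAG]) -> dict[str, int]:
    """For each term, in how many of the corpus DAGs it appears."""
    if not corpus:
        raise ValidationError("membership counts need a non-empty DAG corpus")
    counts: dict[str, int] = {}
    for dag in corpus:
        for t in dag.nodes:
            counts[t] = counts.get(t, 0) + 1
    return counts


def contribution_model2(
    dag: DiseaseDAG,
    counts: Mapping[str, int],
    n_diseases: int,
    base: float | None = None,
) -> ContributionMap:
    """DAG-frequency contributions ``-log(count(t) / n_diseases)``.

    ``base=None`` means the natural logarithm.  The resulting *similarity* is
    base-invariant; semantic values are not.
    """
    if n_diseases <= 0:
        raise ValidationError("n_diseases must be positive")
    values: dict[str, float] = {}
    for t in dag.nodes:
        c = counts.get(t, 0)
        if c <= 0 or c > n_diseases:
            raise ValidationError(
                f"membership count {c} for term {t!r} outside [1, {n_diseases}]"
            )
        v = -math.log(c / n_diseases)
        if base is not None:
            v /= math.log(base)
        values[t] = v
    return ContributionMap(dag.disease, values, model=2)


def similarity_model2(
    dagA: DiseaseDAG,
    dagB: DiseaseDAG,
    contribsA: ContributionMap,
    contribsB: ContributionMap,
) -> float:
    """Model-2 semantic similarity from precomputed frequency contributions.

    Two distinct diseases whose DAGs hold only universally shared terms have
    semantic value 0 on both sides; their similarity is defined as 0 (the
    0/0 guard).  Identity is exactly 1.
    """
    if dagA.disease == dagB.disease:
        return 1.0
    den = sum(contribsA.values.values()) + sum(contribsB.values.values())
    if den == 0:
        return 0.0
    shared = dagA.nodes & dagB.nodes
    num = sum(contribsA.values[t] + contribsB.values[t] for t in shared)
    return num / den


def similarity_matrix(
    ontology: DiseaseOntology,
    diseases: Sequence[str],
    model: int = 1,
    delta: float = DEFAULT_DELTA,
    corpus: Sequence[str] | None = None,
    log_base: float | None = None,
) -> SimilarityMatrix:
    """Full semantic-similarity matrix over an ordered disease list.

    For model 2 the DAG-membership counts are taken over ``corpus`` (term
    ids), defaulting to ``diseases`` itself — i.e. the studied diseases, not
    the whole vocabulary.
    """
    if model not in (1, 2):
        raise ParameterError(f"model must be 1 or 2, got {model}")
    diseases = list(diseases)
    dags = {d: build_dag(ontology, d) for d in diseases}
    n = len(diseases)
    m = np.eye(n)
    if model == 1:
        for a in range(n):
            for b in range(a + 1, n):
                m[a, b] = m[b, a] = similarity_model1(
                    dags[diseases[a]], dags[diseases[b]], delta
                )
    else:
        corpus_ids = list(corpus) if corpus is not None else diseases
        corpus_dags = [dags.get(d) or build_dag(ontology, d) for d in corpus_ids]
        counts = dag_membership_counts(corpus_dags)
        # Terms of studied DAGs can be absent from the corpus counts when an
        # explicit corpus is narrower; treat them as appearing once (their
        # own DAG) to keep contributions defined.
        contribs = {}
        n_corpus = len(corpus_dags)
        for d in diseases:
            cts = {t: counts.get(t, 1) for t in dags[d].nodes}
            contribs[d] = contribution_model2(dags[d], cts, n_corpus, base=log_base)
        for a in range(n):
            for b in range(a + 1, n):
                da, db = diseases[a], diseases[b]
                m[a, b] = m[b, a] = similarity_model2(
                    dags[da], dags[db], contribs[da], contribs[db]
                )
    return SimilarityMatrix(diseases, m).validate()
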