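"""Shared fixtures: toy ontologies and random-instance generators."""

import numpy as np
import pytest

from lncsim import (
    AssociationTable,
    DiseaseOntology,
    build_dag,
)


@pytest.fixture
def toy_ontology():
    """R -> {A, B}, A -> C: the 4-disease worked-example hierarchy."""
    return DiseaseOntology(
        [
            ("R", "root disease", ["C01"]),
            ("A", "disease a", ["C01.1"]),
            ("B", "disease b", ["C01.2"]),
            ("C", "disease c", ["C01.1.1"]),
        ]
    )


@pytest.fixture
def toy_dags(toy_ontology):
    return {d: build_dag(toy_ontology, d) for d in ["R", "A", "B", "C"]}


@pytest.fixture
def toy_assoc():
    """Three lncRNAs with disease groups {C}, {A, B}, {B}."""
    m = np.array(
        [
            [0, 0, 0, 1],  # L1 -> C
            [0, 1, 1, 0],  # L2 -> A, B
            [0, 0, 1, 0],  # L3 -> B
        ]
    )
    return AssociationTable(["L1", "L2", "L3"], ["R", "A", "B", "C"], m)


def random_ontology(rng: np.random.Generator, max_terms: int = 12) -> DiseaseOntology:
    """Random multi-rooted vocabulary; some terms own two codes (diamonds)."""
    n = int(rng.integers(3, max_terms + 1))
    codes = ["C1"]
    if rng.random() < 0.3:
        codes.append("C2")
    while len(codes) < n:
        parent = codes[int(rng.integers(0, len(codes)))]
        child = f"{parent}.{int(rng.integers(1, 9))}"
        if child not in codes:
            codes.append(child)
    terms = []
    used = set(codes)
    for k, code in enumerate(codes):
        terms.append((f"T{k}", f"term {k}", [code]))
    # Give a few terms an extra code to create multi-parent (diamond) shapes.
    # The extra code hangs under an earlier term's code, so every derived
    # parent edge points from a smaller to a larger term index: acyclic by
    # construction.
    for k in range(1, len(terms)):
        if rng.random() >= 0.25:
            continue
        parent = codes[int(rng.integers(0, k))]
        code = f"{parent}.{int(rng.integers(1, 9))}"
        if code not in used:
            used.add(code)
            terms[k][2].append(code)
    return DiseaseOntology(terms)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
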