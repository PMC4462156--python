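"""Disease vocabulary handling: tree numbers, per-disease DAGs, association mapping.

A disease vocabulary in the MeSH Category-C style assigns every term one or
more dot-delimited *tree numbers* (e.g. ``C04.557.337``).  Truncating a tree
number at each dot yields the codes of the term's ancestors, so the hierarchy
is fully determined by the codes themselves: a term with several tree numbers
has several parents and the vocabulary forms a directed acyclic graph from
general (parent) to specific (child) terms.

For a disease ``A`` the subgraph ``DAG(A)`` contains ``A`` itself plus every
ancestor term reachable through the prefixes of *any* of ``A``'s tree numbers,
together with all parent->child edges among those terms.  ``A`` sits in layer
0; an ancestor's layer is the length of the shortest directed path down to
``A``.  These DAGs are the substrate for both semantic-similarity models in
:mod:`lncsim.disease`.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from collections import deque
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .containers import AssociationTable
from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)


def ancestors_of(tree_number: str) -> list[str]:
    """All proper prefixes of a tree number, most general first.

    ``"C04.557.337" -> ["C04", "C04.557"]``.  The input itself is excluded;
    a top-level code has no ancestors.
    """
    if not tree_number:
        raise ValidationError("tree number must be a non-empty code")
    parts = tree_number.split(".")
    return [".".join(parts[:k]) for k in range(1, len(parts))]


@dataclasses.dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    tree_numbers: frozenset[str]


class DiseaseOntology:
    """A validated disease vocabulary with derived parent/child structure.

    Parameters
    ----------
    terms:
        Iterable of ``(term_id, name, tree_numbers)`` triples.  Tree numbers
        must be non-empty; terms without any are rejected (the parser drops
        them before construction, with a warning).

    Notes
    -----
    The parent of a code is its longest proper prefix that resolves to a
    known term; prefixes absent from the vocabulary are skipped (and logged
    once) so that a partial vocabulary still yields a connected ancestry.
    """

    def __init__(self, terms: Iterable[tuple[str, str, Iterable[str]]]):
        self.terms: dict[str, Term] = {}
        self.code_owner: dict[str, str] = {}
        for term_id, name, codes in terms:
            term_id = str(term_id).strip()
            codes = frozenset(str(c).strip() for c in codes if str(c).strip())
            if term_id in self.terms:
                raise ValidationError(f"duplicate term_id {term_id!r}")
            if not codes:
                raise ValidationError(f"term {term_id!r} has no tree numbers")
            for c in codes:
                if c in self.code_owner:
                    raise ValidationError(
                        f"tree number {c!r} claimed by both "
                        f"{self.code_owner[c]!r} and {term_id!r}"
                    )
                self.code_owner[c] = term_id
            self.terms[term_id] = Term(term_id, str(name), codes)
        self._missing_prefixes: set[str] = set()
        self.parents: dict[str, set[str]] = {t: set() for t in self.terms}
        for term in self.terms.values():
            for code in term.tree_numbers:
                parent = self._known_parent_of_code(code, term.term_id)
                if parent is not None:
                    self.parents[term.term_id].add(parent)
        self.children: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                self.children[p].add(child)
        g = nx.DiGraph(
            (p, c) for c, ps in self.parents.items() for p in ps
        )
        if g.number_of_edges() and not nx.is_directed_acyclic_graph(g):
            raise ValidationError("derived parent/child relation is cyclic")
        if self._missing_prefixes:
            logger.warning(
                "%d tree-number prefixes resolve to no known term (skipped): %s",
                len(self._missing_prefixes),
                sorted(self._missing_prefixes)[:10],
            )

    def _known_parent_of_code(self, code: str, owner: str) -> str | None:
        for prefix in reversed(ancestors_of(code)):
            target = self.code_owner.get(prefix)
            if target is None:
                self._missing_prefixes.add(prefix)
            elif target != owner:
                return target
        return None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term_ids(self) -> list[str]:
        return sorted(self.terms)

    def ancestor_terms(self, term_id: str) -> set[str]:
        """Terms owning any proper prefix of any of the term's tree numbers."""
        if term_id not in self.terms:
            raise KeyError(f"unknown disease term {term_id!r}")
        out: set[str] = set()
        for code in self.terms[term_id].tree_numbers:
            for prefix in ancestors_of(code):
                owner = self.code_owner.get(prefix)
                if owner is not None and owner != term_id:
                    out.add(owner)
        return out


@dataclasses.dataclass(frozen=True)
class DiseaseDAG:
    """``DAG(A)``: the disease of interest, its ancestors, and their edges."""

    disease: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    layer: Mapping[str, int]

    def children_within(self, term_id: str) -> set[str]:
        return {c for p, c in self.edges if p == term_id}


def build_dag(ontology: DiseaseOntology, disease: str) -> DiseaseDAG:
    """Construct ``DAG(A)`` for one disease.

    Nodes are the disease plus the union, over all of its tree numbers, of
    the terms owning each proper prefix.  Edges are every parent->child pair
    of the ontology with both endpoints in the node set.  Layers count the
    shortest directed path from a node down to the disease (the disease is
    layer 0).
    """
    if disease not in ontology:
        raise KeyError(f"unknown disease term {disease!r}")
    nodes = frozenset({disease} | ontology.ancestor_terms(disease))
    edges = frozenset(
        (p, c)
        for c in nodes
        for p in ontology.parents[c]
        if p in nodes
    )
    # BFS upward from the disease over child->parent to get shortest hops.
    up: dict[str, set[str]] = {n: set() for n in nodes}
    for p, c in edges:
        up[c].add(p)
    layer: dict[str, int] = {disease: 0}
    queue = deque([disease])
    while queue:
        cur = queue.popleft()
        for p in up[cur]:
            if p not in layer:
                layer[p] = layer[cur] + 1
                queue.append(p)
    for n in nodes - layer.keys():
        # Disconnected ancestor (pathological partial vocabulary): fall back
        # to the code-depth difference so the layer is still defined.
        depths = []
        for tn in ontology.terms[disease].tree_numbers:
            for prefix in ancestors_of(tn):
                if ontology.code_owner.get(prefix) == n:
                    depths.append(len(tn.split(".")) - len(prefix.split(".")))
        layer[n] = min(depths) if depths else 1
        logger.debug("node %r unreachable in DAG(%s); layer from code depth", n, disease)
    return DiseaseDAG(disease, nodes, edges, layer)


def parse_descriptor_table(path) -> DiseaseOntology:
    """Read a descriptor TSV (``term_id  name  tree_numbers``) into an ontology.

    ``tree_numbers`` holds one or more codes separated by ``;``.  Rows whose
    tree-number field is empty are dropped with a warning; a row with the
    wrong number of columns raises :class:`ParseError` naming the line.
    """
    rows: list[tuple[str, str, list[str]]] = []
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "term_id",
            "name",
            "tree_numbers",
        ]:
            raise ParseError(
                f"{path}: expected header 'term_id\\tname\\ttree_numbers'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns, found {len(row)}"
                )
            term_id, name, codes = (c.strip() for c in row)
            code_list = [c.strip() for c in codes.split(";") if c.strip()]
            if not code_list:
                dropped += 1
                logger.warning(
                    "%s:%d: term %r has no tree numbers; dropped", path, lineno, term_id
                )
                continue
            rows.append((term_id, name, code_list))
    if dropped:
        logger.warning("%s: dropped %d rows without tree numbers", path, dropped)
    return DiseaseOntology(rows)


def map_associations(
    raw_pairs: Sequence[tuple[str, str]],
    name_map: Mapping[str, str],
    ontology: DiseaseOntology,
) -> AssociationTable:
    """Map raw (lncRNA name, disease name) records onto vocabulary terms.

    Disease names are lowercased and trimmed before lookup in ``name_map``;
    names that resolve to the same term merge into one column, duplicates
    collapse, and unmapped names are dropped (count logged).  Raises
    :class:`ValidationError` if nothing survives.
    """
    norm_map = {str(k).strip().lower(): v for k, v in name_map.items()}
    lnc_order: list[str] = []
    dis_order: list[str] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    pairs: list[tuple[str, str]] = []
    for lnc, dis in raw_pairs:
        lnc = str(lnc).strip()
        term = norm_map.get(str(dis).strip().lower())
        if term is None or term not in ontology:
            n_dropped += 1
            continue
        if (lnc, term) in seen:
            continue
        seen.add((lnc, term))
        pairs.append((lnc, term))
        if lnc not in lnc_order:
            lnc_order.append(lnc)
        if term not in dis_order:
            dis_order.append(term)
    if n_dropped:
        logger.warning("dropped %d association records with unmapped diseases", n_dropped)
    if not pairs:
        raise ValidationError("no association records survived disease mapping")
    li = {t: k for k, t in enumerate(lnc_order)}
    di = {t: k for k, t in enumerate(dis_order)}
    m = np.zeros((len(lnc_order), len(dis_order)), dtype=np.int8)
    for lnc, term in pairs:
        m[li[lnc], di[term]] = 1
    return AssociationTable(lnc_order, dis_order, m)


def read_association_pairs(path) -> list[tuple[str, str]]:
    """Read an association list TSV with header ``lncrna  disease``."""
    out: list[tuple[str, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["lncrna", "disease"]:
            raise ParseError(f"{path}: expected header 'lncrna\\tdisease'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, found {len(row)}")
            out.append((row[0].strip(), row[1].strip()))
    return out


def read_name_map(path) -> dict[str, str]:
    """Read a name-map TSV with header ``disease_name  term_id``."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["disease_name", "term_id"]:
            raise ParseError(f"{path}: expected header 'disease_name\\tterm_id'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, found {len(row)}")
            out[row[0].strip()] = row[1].strip()
    return out
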