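"""Structural subsumption over EQ definitions.

The fragment implemented is existential-conjunctive (EL-style) plus
top-level unions, which covers every printed entity-quality phenotype
axiom: a definition ``d1`` is subsumed by ``d2`` iff each conjunct of
``d2`` is entailed by the corresponding conjunct of ``d1`` under the
reflexive-transitive is_a closure of the imported entity ontologies:

* ``quality(d1) ⊑* quality(d2)`` in the quality (PATO) graph;
* if ``d2`` constrains the bearer entity, so must ``d1``, with
  ``entity(d1) ⊑* entity(d2)``; likewise for ``towards``;
* an abnormality qualifier on ``d2`` requires one on ``d1``;
* ``d1 ⊑ (A ∪ B)`` iff ``d1 ⊑ A`` or ``d1 ⊑ B``; ``(A ∪ B) ⊑ d2`` iff
  both operands are.

Classifying a document combines these inferred edges with the asserted
is_a links, condenses mutually subsuming terms into equivalence groups
(reported as curator feedback, not errors) and transitively reduces the
result, keeping per-edge provenance (asserted vs inferred).  Assert as
little as possible, infer the rest: the asserted-vs-inferred statistics
quantify how much of the classification the entity ontologies carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, FrozenSet, List, Mapping, Tuple

import networkx as nx

from .errors import CycleError, UnknownTermError
from .eq import EQDefinition
from .graph import TermGraph, transitive_closure, transitive_reduction
from .ids import CurieId
from .obo import OntologyDocument

Edge = Tuple[CurieId, CurieId]

ASSERTED = "asserted"
INFERRED = "inferred"


def _leq(a: CurieId, b: CurieId, imports: Mapping[str, TermGraph], context: str) -> bool:
    """Reflexive-transitive is_a containment ``a ⊑* b`` in the imports."""
    if a == b:
        return True
    ga = imports.get(a.prefix)
    if ga is None or a not in ga:
        raise UnknownTermError(a.obo, context)
    gb = imports.get(b.prefix)
    if gb is None or b not in gb:
        raise UnknownTermError(b.obo, context)
    return b in ga.ancestors(a)


def eq_subsumes(
    d1: EQDefinition, d2: EQDefinition, imports: Mapping[str, TermGraph]
) -> bool:
    """True iff the class described by ``d1`` is a subclass of the class
    described by ``d2``.

    Unresolved fillers raise :class:`UnknownTermError` rather than silently
    answering False.
    """
    if d1.is_union:
        return all(eq_subsumes(op, d2, imports) for op in d1.operands)
    if d2.is_union:
        return any(eq_subsumes(d1, op, imports) for op in d2.operands)
    if d2.quality is not None:
        if d1.quality is None or not _leq(d1.quality, d2.quality, imports, "quality"):
            return False
    if d2.entity is not None:
        if d1.entity is None or not _leq(d1.entity, d2.entity, imports, "inheres_in filler"):
            return False
    if d2.towards is not None:
        if d1.towards is None or not _leq(d1.towards, d2.towards, imports, "towards filler"):
            return False
    if d2.abnormal and not d1.abnormal:
        return False
    return True


@dataclass(frozen=True)
class InferredHierarchy:
    """A transitively reduced direct-subclass DAG with per-edge provenance.

    Terms inferred mutually equivalent are condensed onto their id-least
    representative; the full groups are reported in ``equivalence_groups``.
    """

    direct_edges: Tuple[Edge, ...]
    provenance: Mapping[Edge, str]
    equivalence_groups: Tuple[FrozenSet[CurieId], ...] = ()

    @property
    def closure(self) -> FrozenSet[Edge]:
        """(descendant, ancestor) pairs implied by the direct edges, with
        equivalence groups expanded back onto all member ids."""
        rep: Dict[CurieId, CurieId] = {}
        members: Dict[CurieId, List[CurieId]] = {}
        for group in self.equivalence_groups:
            r = min(group)
            for m in group:
                rep[m] = r
            members[r] = sorted(group)
        base = transitive_closure(self.direct_edges)
        pairs = set()
        for child, parent in base:
            for c in members.get(child, [child]):
                for p in members.get(parent, [parent]):
                    if c != p:
                        pairs.add((c, p))
        for group in self.equivalence_groups:
            for a in group:
                for b in group:
                    if a != b:
                        pairs.add((a, b))
        return frozenset(pairs)

    def superclasses_of(self, term: CurieId, direct: bool = False) -> FrozenSet[CurieId]:
        if direct:
            return frozenset(p for c, p in self.direct_edges if c == term)
        return frozenset(p for c, p in self.closure if c == term)

    def subclasses_of(self, term: CurieId, direct: bool = False) -> FrozenSet[CurieId]:
        """Subclasses of ``term``: direct children of the reduced DAG, or all
        descendants in the closure."""
        if direct:
            return frozenset(c for c, p in self.direct_edges if p == term)
        return frozenset(c for c, p in self.closure if p == term)

    def edge_rows(self) -> List[str]:
        """TSV rows (child, parent, provenance), id-sorted."""
        rows = ["child\tparent\tprovenance"]
        for child, parent in self.direct_edges:
            rows.append(f"{child.obo}\t{parent.obo}\t{self.provenance[(child, parent)]}")
        return rows


def classify(
    doc: OntologyDocument, imports: Mapping[str, TermGraph]
) -> InferredHierarchy:
    """Compute the inferred phenotype hierarchy of a document.

    Equivalent-class definitions generate inferred edges in both directions
    of the subsumption test; necessary-condition-only definitions place
    their term under matching classes but never attract descendants.
    Asserted is_a links are merged in; the result is transitively reduced
    with provenance per surviving edge.
    """
    terms = [t for t in doc.named_terms() if not t.is_obsolete]
    ids = {t.id for t in terms}
    defs: Dict[CurieId, EQDefinition] = {
        t.id: t.definition_expression for t in terms if t.definition_expression is not None
    }
    asserted = {(t.id, p) for t in terms for p in t.is_a if p in ids}

    # asserted cycles are input errors, not equivalence findings
    ag = nx.DiGraph()
    ag.add_nodes_from(ids)
    ag.add_edges_from(asserted)
    if not nx.is_directed_acyclic_graph(ag):
        raise CycleError([u for u, _ in nx.find_cycle(ag)])

    inferred = set()
    sorted_ids = sorted(defs)
    for child in sorted_ids:
        d1 = defs[child]
        for parent in sorted_ids:
            if parent == child:
                continue
            d2 = defs[parent]
            if not d2.equivalence:
                continue  # necessary-only definitions contribute no descendants
            if eq_subsumes(d1, d2, imports):
                inferred.add((child, parent))

    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from(asserted | inferred)

    # condense mutual subsumption onto id-least representatives
    groups = tuple(
        frozenset(scc) for scc in sorted(
            (scc for scc in nx.strongly_connected_components(g) if len(scc) > 1),
            key=min,
        )
    )
    rep: Dict[CurieId, CurieId] = {}
    for group in groups:
        r = min(group)
        for m in group:
            rep[m] = r
    condensed = {
        (rep.get(c, c), rep.get(p, p))
        for c, p in (asserted | inferred)
        if rep.get(c, c) != rep.get(p, p)
    }
    direct = transitive_reduction(condensed)
    asserted_condensed = {
        (rep.get(c, c), rep.get(p, p)) for c, p in asserted if rep.get(c, c) != rep.get(p, p)
    }
    provenance = {
        e: (ASSERTED if e in asserted_condensed else INFERRED) for e in direct
    }
    return InferredHierarchy(
        direct_edges=direct, provenance=provenance, equivalence_groups=groups
    )


@dataclass(frozen=True)
class InferenceStats:
    """Asserted-vs-inferred accounting over the direct (reduced) edges."""

    n_direct: int
    n_inferred: int

    @property
    def fraction_inferred(self) -> Fraction:
        if self.n_direct == 0:
            return Fraction(0)
        return Fraction(self.n_inferred, self.n_direct)

    @property
    def percent_inferred(self) -> int:
        """Integer percent, half-up rounding."""
        if self.n_direct == 0:
            return 0
        return int((200 * self.n_inferred + self.n_direct) // (2 * self.n_direct))

    def rows(self) -> List[str]:
        return [
            "metric\tvalue",
            f"n_direct\t{self.n_direct}",
            f"n_inferred\t{self.n_inferred}",
            f"fraction_inferred\t{float(self.fraction_inferred):.4f}",
            f"percent_inferred\t{self.percent_inferred}",
        ]


def inference_stats(asserted: TermGraph, result: InferredHierarchy) -> InferenceStats:
    """Count direct classifications and how many of them are inferred (i.e.
    absent from the asserted direct-edge set)."""
    n_direct = len(result.direct_edges)
    n_inferred = sum(1 for e in result.direct_edges if e not in asserted.edges)
    return InferenceStats(n_direct=n_direct, n_inferred=n_inferred)
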