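"""DAG model of an ontology's is_a backbone.

Only is_a edges participate in classification.  Other relationships
(part_of, regulates, ...) are carried through I/O untouched but never used
for subsumption: propagating phenotype classification along part_of is
unsound for the entity-quality patterns this toolkit implements.

A :class:`TermGraph` stores direct (child, parent) pairs; ancestor queries
are transitive-closure lookups, module extraction follows the
"all terms on paths to root" import strategy, and transitive reduction
recovers the minimal direct-edge set (the "direct classifications" that
asserted-vs-inferred statistics count).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import FrozenSet, Iterable, Tuple

import networkx as nx

from .errors import CycleError, UnknownTermError
from .ids import CurieId

Edge = Tuple[CurieId, CurieId]


@dataclass(frozen=True)
class TermGraph:
    """An acyclic is_a graph over :class:`CurieId` nodes.

    Edges run child -> parent.  Multiple roots are permitted (the GO has
    three); "paths to root" always means paths to *any* root.
    """

    nodes: FrozenSet[CurieId]
    edges: FrozenSet[Edge]

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], nodes: Iterable[CurieId] = ()) -> "TermGraph":
        edges = frozenset(edges)
        all_nodes = frozenset(nodes) | {n for e in edges for n in e}
        g = cls(nodes=all_nodes, edges=edges)
        g._check_acyclic()
        return g

    def _check_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self._nx):
            cycle = [u for u, _ in nx.find_cycle(self._nx)]
            raise CycleError(cycle)

    @cached_property
    def _nx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @cached_property
    def roots(self) -> FrozenSet[CurieId]:
        """Nodes with no parent."""
        return frozenset(n for n in self.nodes if self._nx.out_degree(n) == 0)

    def __contains__(self, term: CurieId) -> bool:
        return term in self.nodes

    def parents(self, term: CurieId) -> FrozenSet[CurieId]:
        self._require(term)
        return frozenset(self._nx.successors(term))

    def children(self, term: CurieId) -> FrozenSet[CurieId]:
        self._require(term)
        return frozenset(self._nx.predecessors(term))

    def ancestors(self, term: CurieId, reflexive: bool = False) -> FrozenSet[CurieId]:
        """All strict ancestors of ``term`` (its transitive parents).

        With ``reflexive=True`` the term itself is included.
        """
        self._require(term)
        anc = nx.descendants(self._nx, term)  # edges run child -> parent
        if reflexive:
            anc = anc | {term}
        return frozenset(anc)

    def descendants(self, term: CurieId, reflexive: bool = False) -> FrozenSet[CurieId]:
        self._require(term)
        desc = nx.ancestors(self._nx, term)
        if reflexive:
            desc = desc | {term}
        return frozenset(desc)

    def extract_module(self, used: Iterable[CurieId]) -> "TermGraph":
        """Paths-to-root module: the used terms plus everything on some
        child -> ... -> root path from them, with all edges among the
        retained nodes.

        An empty ``used`` set yields the empty graph.
        """
        used = set(used)
        for t in used:
            self._require(t)
        keep: set[CurieId] = set(used)
        for t in used:
            keep |= self.ancestors(t)
        kept_edges = frozenset(e for e in self.edges if e[0] in keep and e[1] in keep)
        return TermGraph(nodes=frozenset(keep), edges=kept_edges)

    def _require(self, term: CurieId) -> None:
        if term not in self.nodes:
            raise UnknownTermError(term.obo)


def transitive_reduction(edges: Iterable[Edge]) -> Tuple[Edge, ...]:
    """Minimal edge set with the same transitive closure, sorted by
    (child, parent) for deterministic output.

    Raises :class:`CycleError` (listing one cycle) on cyclic input.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise CycleError(cycle)
    reduced = nx.transitive_reduction(g)
    return tuple(sorted(reduced.edges()))


def transitive_closure(edges: Iterable[Edge]) -> FrozenSet[Edge]:
    """All (descendant, ancestor) pairs implied by ``edges``."""
    g = nx.DiGraph()
    g.add_edges_from(edges)
    closure = nx.transitive_closure(g)
    return frozenset(closure.edges())
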