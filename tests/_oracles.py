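"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the library's own algorithms: closures
are naive DFS walks, EQ subsumption is an exhaustive conjunct-mapping
search, and Allen relations are classified from integer interval endpoints.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, Set, Tuple

from flypheno.eq import ABNORMAL, EQDefinition
from flypheno.temporal import AllenRelation, OTHER


# ---------------------------------------------------------------------------
# Naive graph closure
# ---------------------------------------------------------------------------


def naive_ancestors(edges: Iterable[Tuple], node) -> Set:
    """Repeated-DFS transitive closure of the child->parent relation."""
    parents: Dict = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    seen: Set = set()
    stack = list(parents.get(node, ()))
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(parents.get(n, ()))
    return seen


def naive_closure(edges: Iterable[Tuple]) -> Set[Tuple]:
    edges = list(edges)
    nodes = {n for e in edges for n in e}
    return {(c, p) for c in nodes for p in naive_ancestors(edges, c)}


# ---------------------------------------------------------------------------
# EQ subsumption by exhaustive conjunct mapping
# ---------------------------------------------------------------------------


def _atoms(d: EQDefinition) -> Set[Tuple[str, object]]:
    atoms: Set[Tuple[str, object]] = set()
    if d.quality is not None:
        atoms.add(("genus", d.quality))
    if d.entity is not None:
        atoms.add(("inheres_in", d.entity))
    if d.towards is not None:
        atoms.add(("towards", d.towards))
    if d.abnormal:
        atoms.add(("qualifier", ABNORMAL))
    return atoms


def _filler_leq(a, b, imports) -> bool:
    if a == b:
        return True
    g = imports.get(a.prefix)
    if g is None:
        return False
    return b in naive_ancestors(g.edges, a)


def homomorphism_subsumes(d1: EQDefinition, d2: EQDefinition, imports) -> bool:
    """d1 ⊑ d2 iff there is a mapping of every conjunct atom of d2 onto some
    atom of d1 with the same role and ancestor-contained filler; unions are
    expanded to disjunctive normal form first."""
    if d1.is_union:
        return all(homomorphism_subsumes(op, d2, imports) for op in d1.operands)
    if d2.is_union:
        return any(homomorphism_subsumes(d1, op, imports) for op in d2.operands)
    atoms1, atoms2 = _atoms(d1), _atoms(d2)
    if not atoms2:
        return True
    # try every total mapping of d2's atoms onto d1's atoms
    for assignment in itertools.product(sorted(atoms1), repeat=len(atoms2)):
        ok = True
        for (role2, filler2), (role1, filler1) in zip(sorted(atoms2), assignment):
            if role1 != role2 or not _filler_leq(filler1, filler2, imports):
                ok = False
                break
        if ok:
            return True
    return False


# ---------------------------------------------------------------------------
# Allen relations from integer interval endpoints
# ---------------------------------------------------------------------------

_SUBSET = {
    "p": AllenRelation.PRECEDES,
    "P": AllenRelation.PRECEDED_BY,
    "m": AllenRelation.MEETS,
    "M": AllenRelation.MET_BY,
    "d": AllenRelation.DURING,
    "s": AllenRelation.STARTS,
    "f": AllenRelation.FINISHES,
    "=": AllenRelation.EQUALS,
}


def rel13(a: Tuple[int, int], b: Tuple[int, int]) -> str:
    """One of the thirteen base relations between proper intervals."""
    (a1, a2), (b1, b2) = a, b
    if a2 < b1:
        return "p"
    if b2 < a1:
        return "P"
    if a2 == b1:
        return "m"
    if b2 == a1:
        return "M"
    if a1 == b1 and a2 == b2:
        return "="
    if a1 == b1:
        return "s" if a2 < b2 else "S"
    if a2 == b2:
        return "f" if a1 > b1 else "F"
    if b1 < a1 and a2 < b2:
        return "d"
    if a1 < b1 and b2 < a2:
        return "D"
    return "o" if a1 < b1 else "O"


def to_subset(rel: str):
    return _SUBSET.get(rel, OTHER)


def grid_composition_table(max_end: int = 8) -> Dict[Tuple, FrozenSet]:
    """Enumerate all interval triples with endpoints in [0, max_end] and
    record, for each ordered pair of subset relations, the set of possible
    A-to-C relations (collapsed onto the subset + OTHER)."""
    intervals = [(i, j) for i in range(max_end + 1) for j in range(i + 1, max_end + 1)]
    pair_rel = {(a, b): rel13(a, b) for a in intervals for b in intervals}
    table: Dict[Tuple, Set] = {}
    for a, b in itertools.product(intervals, repeat=2):
        r1 = to_subset(pair_rel[(a, b)])
        if r1 is OTHER:
            continue
        for c in intervals:
            r2 = to_subset(pair_rel[(b, c)])
            if r2 is OTHER:
                continue
            table.setdefault((r1, r2), set()).add(to_subset(pair_rel[(a, c)]))
    return {k: frozenset(v) for k, v in table.items()}
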