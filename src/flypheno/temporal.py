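"""Allen-interval reasoning over a chain of life stages.

Life-stage ontologies link the major stages (embryonic, larval, pupal,
mature adult ...) into a timeline with ``immediately_preceded_by``, which is
the inverse of Allen's *meets*.  The subset of Allen's thirteen interval
relations used for age reasoning is::

    precedes (p), preceded_by (P), meets (m), met_by (M),
    during (d), starts (s), finishes (f)

plus explicit equality.  ``p``/``P`` and ``m``/``M`` are mutual inverses.
Composition follows the standard Allen composition table (meets and met_by
are *not* transitive; precedes, preceded_by and during are); any composed
base relation falling outside the subset is reported with the marker
:data:`OTHER`.

Death timing is modelled at stage granularity: an organism's death is
assigned to the single stage during which it occurs.  An
:class:`AgeConstraint` denotes a set of permissible death-stage indices —
its canonical semantics — which makes constraint subsumption a subset
check.  ``before_end_of(S)`` is ``during(S) ∪ precedes(S)``; that reading is
what makes the lethal-phase nesting come out.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, FrozenSet, Optional, Tuple, Union

from .errors import FlyphenoError, UnknownTermError
from .ids import CurieId


class AllenRelation(Enum):
    PRECEDES = "p"
    PRECEDED_BY = "P"
    MEETS = "m"
    MET_BY = "M"
    DURING = "d"
    STARTS = "s"
    FINISHES = "f"
    EQUALS = "="

    def __repr__(self) -> str:  # pragma: no cover - cosmetics
        return f"AllenRelation.{self.name}"


#: Marker for composition results outside the seven-relation subset
#: (overlaps, contains, started_by, finished_by and their inverses).
OTHER = "other"

CompositionResult = FrozenSet[Union[AllenRelation, str]]

_INVERSE = {
    AllenRelation.PRECEDES: AllenRelation.PRECEDED_BY,
    AllenRelation.PRECEDED_BY: AllenRelation.PRECEDES,
    AllenRelation.MEETS: AllenRelation.MET_BY,
    AllenRelation.MET_BY: AllenRelation.MEETS,
    AllenRelation.DURING: None,  # inverse (contains) lies outside the subset
    AllenRelation.STARTS: None,
    AllenRelation.FINISHES: None,
    AllenRelation.EQUALS: AllenRelation.EQUALS,
}


def inverse(r: AllenRelation) -> Union[AllenRelation, str]:
    """Inverse relation, or :data:`OTHER` if it falls outside the subset."""
    inv = _INVERSE[r]
    return inv if inv is not None else OTHER


_p = AllenRelation.PRECEDES
_P = AllenRelation.PRECEDED_BY
_m = AllenRelation.MEETS
_M = AllenRelation.MET_BY
_d = AllenRelation.DURING
_s = AllenRelation.STARTS
_f = AllenRelation.FINISHES
_e = AllenRelation.EQUALS

_ALL: CompositionResult = frozenset({_p, _P, _m, _M, _d, _s, _f, _e, OTHER})

# Standard Allen composition restricted to the subset; base relations outside
# the subset collapse onto OTHER.  Verified against integer-grid interval
# enumeration in the test suite.
_COMPOSE: Dict[Tuple[AllenRelation, AllenRelation], CompositionResult] = {
    (_p, _p): frozenset({_p}),
    (_p, _P): _ALL,
    (_p, _m): frozenset({_p}),
    (_p, _M): frozenset({_p, _m, _d, _s, OTHER}),
    (_p, _d): frozenset({_p, _m, _d, _s, OTHER}),
    (_p, _s): frozenset({_p}),
    (_p, _f): frozenset({_p, _m, _d, _s, OTHER}),
    (_P, _p): _ALL,
    (_P, _P): frozenset({_P}),
    (_P, _m): frozenset({_P, _M, _d, _f, OTHER}),
    (_P, _M): frozenset({_P}),
    (_P, _d): frozenset({_P, _M, _d, _f, OTHER}),
    (_P, _s): frozenset({_P, _M, _d, _f, OTHER}),
    (_P, _f): frozenset({_P}),
    (_m, _p): frozenset({_p}),
    (_m, _P): frozenset({_P, _M, OTHER}),
    (_m, _m): frozenset({_p}),
    (_m, _M): frozenset({_f, _e, OTHER}),
    (_m, _d): frozenset({_d, _s, OTHER}),
    (_m, _s): frozenset({_m}),
    (_m, _f): frozenset({_d, _s, OTHER}),
    (_M, _p): frozenset({_p, _m, OTHER}),
    (_M, _P): frozenset({_P}),
    (_M, _m): frozenset({_s, _e, OTHER}),
    (_M, _M): frozenset({_P}),
    (_M, _d): frozenset({_d, _f, OTHER}),
    (_M, _s): frozenset({_d, _f, OTHER}),
    (_M, _f): frozenset({_M}),
    (_d, _p): frozenset({_p}),
    (_d, _P): frozenset({_P}),
    (_d, _m): frozenset({_p}),
    (_d, _M): frozenset({_P}),
    (_d, _d): frozenset({_d}),
    (_d, _s): frozenset({_d}),
    (_d, _f): frozenset({_d}),
    (_s, _p): frozenset({_p}),
    (_s, _P): frozenset({_P}),
    (_s, _m): frozenset({_p}),
    (_s, _M): frozenset({_M}),
    (_s, _d): frozenset({_d}),
    (_s, _s): frozenset({_s}),
    (_s, _f): frozenset({_d}),
    (_f, _p): frozenset({_p}),
    (_f, _P): frozenset({_P}),
    (_f, _m): frozenset({_m}),
    (_f, _M): frozenset({_P}),
    (_f, _d): frozenset({_d}),
    (_f, _s): frozenset({_d}),
    (_f, _f): frozenset({_f}),
}


def compose(r1: AllenRelation, r2: AllenRelation) -> CompositionResult:
    """Composition ``r1 ; r2``: the possible relations between A and C given
    ``A r1 B`` and ``B r2 C``.  Equality is the identity element."""
    if r1 is _e:
        return frozenset({r2})
    if r2 is _e:
        return frozenset({r1})
    return _COMPOSE[(r1, r2)]


# ---------------------------------------------------------------------------
# Stage chains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stage:
    id: CurieId
    label: str


@dataclass(frozen=True)
class StageChain:
    """A linearly ordered set of life stages, stage i+1 meeting stage i
    (``immediately_preceded_by``).  The final stage is taken to be mature
    adulthood; everything before it is "pre-adult"."""

    stages: Tuple[Stage, ...]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise FlyphenoError("a stage chain needs at least 2 stages")
        if len({s.id for s in self.stages}) != len(self.stages):
            raise FlyphenoError("duplicate stages in chain")

    @classmethod
    def from_obo_document(cls, doc, relation: str = "immediately_preceded_by") -> "StageChain":
        """Reconstruct the chain from stage terms linked by
        ``relationship: immediately_preceded_by`` lines."""
        prev_of: Dict[CurieId, CurieId] = {}
        terms = {t.id: t for t in doc.terms if not t.is_obsolete}
        for t in terms.values():
            for rel, target in t.relationships:
                if rel == relation:
                    if t.id in prev_of:
                        raise FlyphenoError(f"{t.id.obo}: more than one {relation} link")
                    prev_of[t.id] = target
        preceded = set(prev_of.values())
        # the first stage is linked-to but carries no link of its own
        first = [i for i in terms if i not in prev_of and i in preceded]
        if len(first) != 1:
            raise FlyphenoError(f"cannot identify a unique first stage (candidates: {sorted(i.obo for i in first)})")
        order = [first[0]]
        succ_of = {v: k for k, v in prev_of.items()}
        while order[-1] in succ_of:
            nxt = succ_of[order[-1]]
            if nxt in order:
                raise FlyphenoError("stage links form a cycle")
            order.append(nxt)
        if len(order) != len(prev_of) + 1:
            raise FlyphenoError("stage links do not form a single chain")
        return cls(tuple(Stage(i, terms[i].label or i.obo) for i in order))

    def __len__(self) -> int:
        return len(self.stages)

    def index(self, stage: Union[Stage, CurieId]) -> int:
        sid = stage.id if isinstance(stage, Stage) else stage
        for i, s in enumerate(self.stages):
            if s.id == sid:
                return i
        raise UnknownTermError(sid.obo, "stage not in chain")

    def stage(self, i: int) -> Stage:
        return self.stages[i]

    @property
    def final_stage(self) -> Stage:
        return self.stages[-1]

    @property
    def pre_adult(self) -> Tuple[Stage, ...]:
        return self.stages[:-1]


def stage_relation(chain: StageChain, a: Union[Stage, CurieId], b: Union[Stage, CurieId]) -> AllenRelation:
    """Allen relation between two stages of the chain: adjacent stages meet,
    non-adjacent ones precede/are preceded by each other."""
    ia, ib = chain.index(a), chain.index(b)
    if ia == ib:
        return AllenRelation.EQUALS
    if ib == ia + 1:
        return AllenRelation.MEETS
    if ib > ia + 1:
        return AllenRelation.PRECEDES
    if ib == ia - 1:
        return AllenRelation.MET_BY
    return AllenRelation.PRECEDED_BY


# ---------------------------------------------------------------------------
# Age constraints
# ---------------------------------------------------------------------------


class AgeForm(Enum):
    PRECEDES = "precedes"
    DURING = "during"
    BEFORE_END_OF = "before_end_of"
    ANY = "any"


@dataclass(frozen=True)
class AgeConstraint:
    """A constraint on the stage during which death occurs, denoting a set
    of stage indices (its canonical semantics, see :func:`index_set`)."""

    form: AgeForm
    stage: Optional[CurieId] = None

    def __post_init__(self) -> None:
        if self.form is AgeForm.ANY:
            if self.stage is not None:
                raise FlyphenoError("'any' carries no stage")
        elif self.stage is None:
            raise FlyphenoError(f"{self.form.value} requires a stage")

    @classmethod
    def precedes(cls, stage: Union[Stage, CurieId]) -> "AgeConstraint":
        return cls(AgeForm.PRECEDES, stage.id if isinstance(stage, Stage) else stage)

    @classmethod
    def during(cls, stage: Union[Stage, CurieId]) -> "AgeConstraint":
        return cls(AgeForm.DURING, stage.id if isinstance(stage, Stage) else stage)

    @classmethod
    def before_end_of(cls, stage: Union[Stage, CurieId]) -> "AgeConstraint":
        return cls(AgeForm.BEFORE_END_OF, stage.id if isinstance(stage, Stage) else stage)

    @classmethod
    def any(cls) -> "AgeConstraint":
        return cls(AgeForm.ANY)

    def describe(self, chain: StageChain) -> str:
        if self.form is AgeForm.ANY:
            return "at any stage"
        label = chain.stage(chain.index(self.stage)).label
        if self.form is AgeForm.PRECEDES:
            return f"before {label}"
        if self.form is AgeForm.DURING:
            return f"during {label}"
        return f"before end of {label}"


def index_set(chain: StageChain, c: AgeConstraint) -> FrozenSet[int]:
    """The set of death-stage indices a constraint permits."""
    if c.form is AgeForm.ANY:
        return frozenset(range(len(chain)))
    k = chain.index(c.stage)
    if c.form is AgeForm.PRECEDES:
        return frozenset(range(k))
    if c.form is AgeForm.DURING:
        return frozenset({k})
    return frozenset(range(k + 1))  # before_end_of = during ∪ precedes


def age_subsumes(chain: StageChain, c1: AgeConstraint, c2: AgeConstraint) -> bool:
    """``c1 ⊑ c2`` iff every death time permitted by c1 is permitted by c2."""
    return index_set(chain, c1) <= index_set(chain, c2)
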