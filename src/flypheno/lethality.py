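"""Lethal-phase terms: mortality-rate bands over age-constrained populations.

A lethal-phase class describes a population of organisms (every member
subject to the same age constraint) together with an *increased mortality
rate*: the percent of the population dying in excess of the wild-type rate
for the same stage window, recorded as a whole number 0-100 (fractional
values are excluded by the datatype).  The default quantifier bands are

* some  — at least 5% (the hard non-zero floor for 'increased mortality');
* most  — at least 50%;
* all   — at least 98% ('lethal' tolerates rare escapers).

For each pre-adult stage S the generator emits the six combinations
{some, most, all} x {die during S, die before the end of S}, plus three
stage-spanning core terms:

* 'increased mortality'            band [5, 100], any age;
* 'lethal'                         band [98, 100], death before mature adulthood;
* 'partially lethal - majority die' band [51, 98] (printed ">50, <= 98"),
  death before mature adulthood.

The generated list is completely flat — no parent links — and acquires its
deeply nested classification purely by reasoning: ``t1 ⊑ t2`` iff t1's band
is contained in t2's band *and* t1's age window is contained in t2's.  A
finite-population model checker provides an independent semantic oracle for
that rule.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx

from .classify import INFERRED, InferredHierarchy
from .errors import FlyphenoError, UnknownTermError
from .graph import transitive_reduction
from .ids import CurieId
from .temporal import AgeConstraint, AgeForm, StageChain, index_set

# Ids the printed axioms attach to the core terms.
INCREASED_MORTALITY_ID = CurieId("FBcv", "0002004")
LETHAL_ID = CurieId("FBcv", "0000351")
PARTIALLY_LETHAL_ID = CurieId("FBcv", "0000352")
SHORT_LIVED_ID = CurieId("FBcv", "0000385")

#: Reserved prefix for deterministically minted per-stage terms.
MINTED_PREFIX = "LP"


@dataclass(frozen=True)
class MortalityRange:
    """A closed integer interval of increased-mortality percentages.

    Strict printed bounds are normalised on parse: ``>50`` becomes lo=51,
    ``<98`` becomes hi=97; the normalisation is lossless over the integer
    datatype.
    """

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi <= 100):
            raise FlyphenoError(f"invalid mortality range [{self.lo}, {self.hi}]")
        if self.lo != int(self.lo) or self.hi != int(self.hi):
            raise FlyphenoError("mortality bounds are whole numbers")

    @classmethod
    def from_text(cls, text: str) -> "MortalityRange":
        """Parse printed bound syntax: ``>=5``, ``>50, <= 98``,
        ``short[>=98]`` ..."""
        inner = text.strip()
        if inner.startswith("short"):
            inner = inner[len("short"):].strip()
        inner = inner.strip("[]")
        lo, hi = 0, 100
        for part in inner.split(","):
            part = part.replace(" ", "")
            if not part:
                continue
            if part.startswith(">="):
                lo = max(lo, int(part[2:]))
            elif part.startswith("<="):
                hi = min(hi, int(part[2:]))
            elif part.startswith(">"):
                lo = max(lo, int(part[1:]) + 1)
            elif part.startswith("<"):
                hi = min(hi, int(part[1:]) - 1)
            else:
                raise FlyphenoError(f"cannot parse mortality bound {part!r}")
        return cls(lo, hi)

    def to_text(self) -> str:
        return f">={self.lo}, <={self.hi}"

    def __contains__(self, value: int) -> bool:
        return self.lo <= value <= self.hi

    def issubset(self, other: "MortalityRange") -> bool:
        return other.lo <= self.lo and self.hi <= other.hi


@dataclass(frozen=True)
class PopulationConstraint:
    """The age constraint every member of the population satisfies (the
    ``has_member some`` / ``has_member only`` pattern over organisms)."""

    age: AgeConstraint


@dataclass(frozen=True)
class Thresholds:
    some: int = 5
    most: int = 50
    all_: int = 98

    def __post_init__(self) -> None:
        if not (0 < self.some <= self.most <= self.all_ <= 100):
            raise FlyphenoError("thresholds must satisfy 0 < some <= most <= all <= 100")


@dataclass(frozen=True)
class LethalPhaseTerm:
    id: CurieId
    label: str
    range: MortalityRange
    population: PopulationConstraint

    @property
    def age(self) -> AgeConstraint:
        return self.population.age


def _mint_id(quantifier: str, mode: str, stage: CurieId, taken: Set[CurieId]) -> CurieId:
    """Deterministic id from (quantifier, mode, stage): stable across runs,
    collision-resolved by linear probing."""
    digest = hashlib.sha1(f"{quantifier}|{mode}|{stage.short_form}".encode()).hexdigest()
    n = int(digest, 16) % 10**7
    while True:
        cid = CurieId(MINTED_PREFIX, f"{n:07d}")
        if cid not in taken:
            return cid
        n = (n + 1) % 10**7


def generate_lethal_phase_terms(
    chain: StageChain,
    thresholds: Thresholds = Thresholds(),
    include_short_lived: bool = False,
) -> List[LethalPhaseTerm]:
    """Generate the flat lethal-phase term set for a stage chain.

    Per pre-adult stage: {some, most, all} x {during, before end of}; plus
    'increased mortality', 'lethal' and 'partially lethal - majority die'.
    'short lived' (increased mortality during the final, adult stage) is
    generated only on request: its printed definition carries no axiom, so
    the encoding is this toolkit's reading.
    """
    if len(chain) < 2:
        raise FlyphenoError("chain lacking a final adult stage")
    terms: List[LethalPhaseTerm] = []
    taken: Set[CurieId] = {INCREASED_MORTALITY_ID, LETHAL_ID, PARTIALLY_LETHAL_ID, SHORT_LIVED_ID}

    bands = (
        ("some", "some die", MortalityRange(thresholds.some, 100)),
        ("most", "majority die", MortalityRange(thresholds.most, 100)),
        ("all", "lethal - all die", MortalityRange(thresholds.all_, 100)),
    )
    for stage in chain.pre_adult:
        for quantifier, phrase, band in bands:
            for mode, age in (
                ("during", AgeConstraint.during(stage)),
                ("before_end_of", AgeConstraint.before_end_of(stage)),
            ):
                tid = _mint_id(quantifier, mode, stage.id, taken)
                taken.add(tid)
                wording = "during" if mode == "during" else "before end of"
                terms.append(
                    LethalPhaseTerm(
                        id=tid,
                        label=f"{phrase} {wording} {stage.label}",
                        range=band,
                        population=PopulationConstraint(age),
                    )
                )
    adult = chain.final_stage
    terms.append(
        LethalPhaseTerm(
            id=INCREASED_MORTALITY_ID,
            label="increased mortality",
            range=MortalityRange.from_text(">=5"),
            population=PopulationConstraint(AgeConstraint.any()),
        )
    )
    terms.append(
        LethalPhaseTerm(
            id=LETHAL_ID,
            label="lethal",
            range=MortalityRange(thresholds.all_, 100),
            population=PopulationConstraint(AgeConstraint.precedes(adult)),
        )
    )
    terms.append(
        LethalPhaseTerm(
            id=PARTIALLY_LETHAL_ID,
            label="partially lethal - majority die",
            range=MortalityRange.from_text(f">{thresholds.most}, <={thresholds.all_}"),
            population=PopulationConstraint(AgeConstraint.precedes(adult)),
        )
    )
    if include_short_lived:
        terms.append(
            LethalPhaseTerm(
                id=SHORT_LIVED_ID,
                label="short lived",
                range=MortalityRange.from_text(">=5"),
                population=PopulationConstraint(AgeConstraint.during(adult)),
            )
        )
    return sorted(terms, key=lambda t: t.id)


def _check_chain(term: LethalPhaseTerm, chain: StageChain) -> None:
    if term.age.form is not AgeForm.ANY:
        chain.index(term.age.stage)  # raises UnknownTermError on mismatch


def lethal_subsumes(t1: LethalPhaseTerm, t2: LethalPhaseTerm, chain: StageChain) -> bool:
    """``t1 ⊑ t2`` iff band containment and age-window containment both hold."""
    _check_chain(t1, chain)
    _check_chain(t2, chain)
    if not t1.range.issubset(t2.range):
        return False
    return index_set(chain, t1.age) <= index_set(chain, t2.age)


def classify_lethal(
    terms: Sequence[LethalPhaseTerm], chain: StageChain
) -> InferredHierarchy:
    """Pairwise subsumption closure of a term set, transitively reduced.

    Mutually subsuming terms are condensed into equivalence groups (e.g.
    'lethal' and 'all die before end of' the last pre-adult stage denote the
    same class).  All provenance is inferred: the input is flat.
    """
    ids = {t.id for t in terms}
    if len(ids) != len(terms):
        raise FlyphenoError("lethal-phase terms must be distinct")
    by_id = {t.id: t for t in terms}
    edges = set()
    for a in sorted(ids):
        for b in sorted(ids):
            if a != b and lethal_subsumes(by_id[a], by_id[b], chain):
                edges.add((a, b))
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from(edges)
    groups = tuple(
        frozenset(scc)
        for scc in sorted(
            (scc for scc in nx.strongly_connected_components(g) if len(scc) > 1), key=min
        )
    )
    rep: Dict[CurieId, CurieId] = {}
    for group in groups:
        r = min(group)
        for m in group:
            rep[m] = r
    condensed = {
        (rep.get(c, c), rep.get(p, p)) for c, p in edges if rep.get(c, c) != rep.get(p, p)
    }
    direct = transitive_reduction(condensed)
    provenance = {e: INFERRED for e in direct}
    return InferredHierarchy(direct_edges=direct, provenance=provenance, equivalence_groups=groups)


# ---------------------------------------------------------------------------
# Finite-population model checking (independent semantic oracle)
# ---------------------------------------------------------------------------

#: Coarse mortality grid: the band boundaries and their neighbours.
MORTALITY_GRID = (5, 50, 51, 97, 98, 100)

_SURVIVES = -1


@lru_cache(maxsize=None)
def _populations(n_stages: int, max_cohorts: int) -> Tuple[Tuple[int, ...], ...]:
    """All distinct per-stage mortality mass vectors realisable by up to
    ``max_cohorts`` cohorts, each a (weight, fate) pair with weight drawn
    from the coarse grid and fate a death stage or survival; total weight
    capped at 100."""
    fates = list(range(n_stages)) + [_SURVIVES]
    cohorts = [(w, f) for w in MORTALITY_GRID for f in fates]
    seen: Set[Tuple[int, ...]] = {tuple([0] * n_stages)}
    for size in range(1, max_cohorts + 1):
        for combo in itertools.combinations_with_replacement(cohorts, size):
            if sum(w for w, _ in combo) > 100:
                continue
            mass = [0] * n_stages
            for w, f in combo:
                if f != _SURVIVES:
                    mass[f] += w
            seen.add(tuple(mass))
    return tuple(sorted(seen))


def _satisfies(mass: Tuple[int, ...], term: LethalPhaseTerm, chain: StageChain) -> bool:
    window = index_set(chain, term.age)
    return sum(mass[i] for i in window) in term.range


def model_check_subsumption(
    t1: LethalPhaseTerm,
    t2: LethalPhaseTerm,
    chain: StageChain,
    population_sizes: Iterable[int] = (1, 2, 3, 4),
) -> bool:
    """Semantic subsumption by exhaustive finite-population enumeration.

    True iff every enumerated population satisfying t1's (band, age window)
    description also satisfies t2's.  This is deliberately independent of
    :func:`lethal_subsumes`' interval arithmetic.
    """
    sizes = sorted(set(population_sizes))
    if not sizes or sizes[0] < 1 or sizes[-1] > 4:
        raise FlyphenoError("population sizes must be small (1-4) for tractability")
    _check_chain(t1, chain)
    _check_chain(t2, chain)
    for mass in _populations(len(chain), sizes[-1]):
        if _satisfies(mass, t1, chain) and not _satisfies(mass, t2, chain):
            return False
    return True


# ---------------------------------------------------------------------------
# Annotation of mortality observations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MortalityObservation:
    """Per-stage increased-mortality percentages (whole numbers, wild-type
    baseline already excluded).  Stages absent from the mapping count as 0."""

    rates: Mapping[CurieId, int]

    def __post_init__(self) -> None:
        for sid, value in self.rates.items():
            if not (0 <= value <= 100) or value != int(value):
                raise FlyphenoError(f"{sid.obo}: mortality {value!r} outside 0-100 whole numbers")

    @classmethod
    def from_tsv(cls, text: str) -> "MortalityObservation":
        """Two-column TSV: stage id, percent.  Lines starting '#' skipped."""
        rates: Dict[CurieId, int] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FlyphenoError(f"malformed observation line: {line!r}")
            rates[CurieId.parse(parts[0])] = int(parts[1])
        return cls(rates)

    def mass_vector(self, chain: StageChain) -> Tuple[int, ...]:
        mass = [0] * len(chain)
        for sid, value in self.rates.items():
            mass[chain.index(sid)] = value
        if sum(mass) > 100:
            raise FlyphenoError("per-stage mortality sums above 100%")
        return tuple(mass)


def annotate_mortality(
    obs: MortalityObservation,
    terms: Sequence[LethalPhaseTerm],
    chain: StageChain,
) -> FrozenSet[CurieId]:
    """The most specific lethal-phase terms an observation supports.

    A term applies iff the observed mortality mass inside its age window
    falls in its band; the result is the antichain of applicable terms under
    subsumption (strict ancestors of another applicable term are dropped).
    """
    missing = [s.id.obo for s in chain.pre_adult if s.id not in obs.rates]
    if missing:
        raise FlyphenoError(f"observation lacks pre-adult stages: {', '.join(missing)}")
    mass = obs.mass_vector(chain)
    applicable = [t for t in terms if _satisfies(mass, t, chain)]
    undominated: List[LethalPhaseTerm] = []
    for t in applicable:
        dominated = any(
            u is not t and lethal_subsumes(u, t, chain) and not lethal_subsumes(t, u, chain)
            for u in applicable
        )
        if not dominated:
            undominated.append(t)
    # collapse mutually equivalent survivors (e.g. during vs before-end-of
    # the first stage) onto one representative, preferring the tighter
    # age-window wording
    rank = {AgeForm.DURING: 0, AgeForm.BEFORE_END_OF: 1, AgeForm.PRECEDES: 2, AgeForm.ANY: 3}
    keep: List[LethalPhaseTerm] = []
    for t in undominated:
        equivalents = [
            u for u in undominated
            if lethal_subsumes(u, t, chain) and lethal_subsumes(t, u, chain)
        ]
        best = min(equivalents, key=lambda u: (rank[u.age.form], u.id))
        if best is t:
            keep.append(t)
    return frozenset(t.id for t in keep)
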