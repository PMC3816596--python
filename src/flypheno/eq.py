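"""Entity-quality (EQ) phenotype definitions.

A phenotype class is formalised as a PATO quality, optionally inhering in an
entity (a GO process, a cell type, an anatomical structure), optionally
qualified as *abnormal* (deviation from wild-type) and optionally directed
``towards`` a second entity (used by relational qualities such as
'has extra parts of type').  In description-logic terms::

    quality  and  inheres_in some E  and  qualifier some abnormal
             and  towards some T

The phenotype root itself is the pattern ``quality and qualifier some
abnormal``: every abnormal-qualified definition entails it.

Two variants extend the basic conjunctive pattern:

* unions — a class equivalent to a disjunction of patterns (e.g. a defect in
  either a process or in its regulation);
* necessary-condition-only definitions, which place a term *under* matching
  classes but never pull other terms under it.

This module also implements the automated textual-definition generator: for
classes defined with the plain ``quality / inheres_in GO process / abnormal``
pattern and lacking a manually supplied definition, a human-readable
definition is derived from the GO term's label and definition so it stays
current as the GO changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Mapping, Optional, Tuple

from .errors import PatternError
from .graph import TermGraph
from .ids import CurieId

if TYPE_CHECKING:  # pragma: no cover
    from .obo import OntologyDocument

# Well-known identifiers used by the patterns.
QUALITY = CurieId("PATO", "0000001")
ABNORMAL = CurieId("PATO", "0000460")

INHERES_IN = "inheres_in"
QUALIFIER = "qualifier"
TOWARDS = "towards"


@dataclass(frozen=True)
class EQDefinition:
    """An EQ class expression (value semantics, hashable).

    A *union* definition carries only ``operands`` (two or more member
    patterns); a non-union carries a ``quality`` genus plus optional
    fillers.  ``equivalence`` distinguishes equivalent-class definitions
    from necessary-condition-only ones.
    """

    quality: Optional[CurieId] = None
    entity: Optional[CurieId] = None
    towards: Optional[CurieId] = None
    abnormal: bool = False
    operands: Tuple["EQDefinition", ...] = ()
    equivalence: bool = True

    def __post_init__(self) -> None:
        if self.operands and (self.quality or self.entity or self.towards or self.abnormal):
            raise PatternError("a union definition carries no quality/entity fields of its own")

    @property
    def is_union(self) -> bool:
        return bool(self.operands)

    def fillers(self) -> Tuple[CurieId, ...]:
        """Every identifier referenced by the expression (recursively)."""
        if self.is_union:
            out: List[CurieId] = []
            for op in self.operands:
                out.extend(op.fillers())
            return tuple(out)
        ids = [i for i in (self.quality, self.entity, self.towards) if i is not None]
        if self.abnormal:
            ids.append(ABNORMAL)
        return tuple(ids)


#: The root 'phenotype' pattern: an abnormal quality of anything.
PHENOTYPE_ROOT_DEFINITION = EQDefinition(quality=QUALITY, abnormal=True, equivalence=True)


@dataclass(frozen=True)
class Finding:
    """A validation finding (never an exception): machine-readable code,
    subject id and human message."""

    code: str
    subject: str
    message: str

    def as_tsv_row(self) -> str:
        return f"{self.code}\t{self.subject}\t{self.message}"


def validate_definition(
    definition: EQDefinition,
    imports: Mapping[str, TermGraph],
    subject: str = "-",
) -> List[Finding]:
    """Check an EQ definition against the loaded import graphs.

    Returns a list of findings; an empty list means the definition is valid.
    Unresolvable fillers, empty or singleton unions and ``towards`` without a
    quality genus are all reported rather than raised.
    """
    findings: List[Finding] = []
    _validate(definition, imports, subject, findings)
    return findings


def _validate(d: EQDefinition, imports, subject: str, findings: List[Finding]) -> None:
    if d.is_union:
        if len(d.operands) < 2:
            findings.append(
                Finding("singleton-union", subject, "union definition with fewer than 2 operands")
            )
        for op in d.operands:
            _validate(op, imports, subject, findings)
        return
    if d.quality is None:
        findings.append(Finding("missing-quality", subject, "non-union definition lacks a quality genus"))
    if d.towards is not None and d.quality is None:
        findings.append(Finding("towards-without-quality", subject, "towards filler without a quality"))
    for filler in d.fillers():
        if filler == ABNORMAL:
            continue  # built into the pattern language, not an import
        g = imports.get(filler.prefix)
        if g is None or filler not in g:
            findings.append(
                Finding("unresolved-filler", subject, f"filler {filler.obo} not found in imports")
            )


# ---------------------------------------------------------------------------
# Automated textual definitions
# ---------------------------------------------------------------------------

_TEMPLATE = (
    "A phenotype that is a defect in '{label}' ({short}). "
    "The GO term '{label}' is defined as: '{definition}'"
)


def derive_textual_definition(go_id: CurieId, go_label: str, go_definition: str) -> str:
    """Render the automated textual definition for a process phenotype.

    Produces exactly::

        A phenotype that is a defect in '<label>' (<PREFIX_NNNNNNN>). The GO
        term '<label>' is defined as: '<definition>'

    using plain ASCII apostrophes.  An empty GO definition is an error (the
    template would emit an empty quote).
    """
    if not go_definition or not go_definition.strip():
        raise PatternError(f"{go_id.obo} has no textual definition to quote")
    if not go_label or not go_label.strip():
        raise PatternError(f"{go_id.obo} has no label")
    return _TEMPLATE.format(label=go_label, short=go_id.short_form, definition=go_definition)


def auto_definition_applies(definition: Optional[EQDefinition]) -> bool:
    """Whether a term's formal definition matches the simple pattern the
    generator supports: ``quality and inheres_in some <GO term> and qualifier
    some abnormal``, as an equivalent-class definition.

    Definitions whose genus is more specific than bare 'quality' are
    excluded: deriving readable text for those has proven unreliable.
    """
    if definition is None or definition.is_union or not definition.equivalence:
        return False
    return (
        definition.quality == QUALITY
        and definition.abnormal
        and definition.entity is not None
        and definition.entity.prefix == "GO"
        and definition.towards is None
    )


def roll_textual_definitions(
    doc: "OntologyDocument",
    go_terms: Mapping[CurieId, Tuple[str, str]],
) -> List[CurieId]:
    """Fill in automated textual definitions across a document, in place.

    ``go_terms`` maps GO ids to (label, textual definition).  Only terms that
    match the simple pattern *and* carry no manually supplied definition are
    touched; the operation is idempotent.  Returns the ids of terms updated.
    """
    updated: List[CurieId] = []
    for term in doc.terms:
        if term.textual_definition:
            continue
        if not auto_definition_applies(term.definition_expression):
            continue
        go_id = term.definition_expression.entity
        if go_id not in go_terms:
            continue
        label, definition = go_terms[go_id]
        if not definition:
            continue
        term.textual_definition = derive_textual_definition(go_id, label, definition)
        term.definition_xrefs = (go_id.obo,)
        updated.append(term.id)
    return updated
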