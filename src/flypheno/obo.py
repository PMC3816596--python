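"""Reading and writing OBO 1.4 ontology files.

The dialect handled here is the subset used by pattern-formalised phenotype
ontologies:

* ``[Term]`` stanzas with ``id``, ``name``, ``def``, ``namespace``,
  ``subset``, ``is_a``, ``relationship`` and ``is_obsolete`` tags;
* genus-differentia EQ definitions encoded as ``intersection_of`` lines —
  one bare genus line (the PATO quality) plus role lines for ``inheres_in``,
  ``qualifier`` and ``towards`` fillers;
* two custom tags, registered in the header via ``subsetdef``-style lines so
  third-party parsers skip them safely:

  - ``equivalent_union_of: <id> <id> ...`` — an equivalent-class union whose
    operands are auxiliary anonymous-pattern stanzas (tagged with
    ``subset: anonymous_pattern``) carrying their own intersection_of lines;
  - ``necessary_pattern: ...`` — same line grammar as ``intersection_of``
    but asserting a necessary condition only.

Unknown tags are preserved as opaque lines and round-trip untouched.  The
writer is deterministic: terms sorted by id, tags in a fixed order, so two
writes of the same document are byte-identical.  A ``simple`` flavour emits a
pre-reasoned release: only is_a links taken from a supplied (transitively
reduced) inferred hierarchy, with all pattern machinery dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import DanglingReferenceError, DuplicateTermError, OboParseError, PatternError
from .eq import ABNORMAL, EQDefinition, INHERES_IN, QUALIFIER, TOWARDS
from .ids import CurieId

ANONYMOUS_PATTERN_SUBSET = "anonymous_pattern"
UNION_TAG = "equivalent_union_of"
NECESSARY_TAG = "necessary_pattern"

_EQ_ROLES = (INHERES_IN, QUALIFIER, TOWARDS)

# subsetdef-style registrations emitted whenever the corresponding feature is
# present, so that the custom tags are declared in-band.
_REGISTRATIONS = {
    ANONYMOUS_PATTERN_SUBSET: (
        f'subsetdef: {ANONYMOUS_PATTERN_SUBSET} '
        '"Auxiliary operand stanza of an equivalent_union_of definition; not a curation target"'
    ),
    UNION_TAG: (
        f'subsetdef: {UNION_TAG} '
        '"Custom tag: equivalent-class union of the named anonymous-pattern stanzas"'
    ),
    NECESSARY_TAG: (
        f'subsetdef: {NECESSARY_TAG} '
        '"Custom tag: necessary-condition-only entity-quality pattern line"'
    ),
}


@dataclass
class OntologyTerm:
    """One ``[Term]`` stanza."""

    id: CurieId
    label: Optional[str] = None
    textual_definition: Optional[str] = None
    definition_xrefs: Tuple[str, ...] = ()
    namespace: Optional[str] = None
    is_a: List[CurieId] = field(default_factory=list)
    relationships: List[Tuple[str, CurieId]] = field(default_factory=list)
    definition_expression: Optional[EQDefinition] = None
    union_operands: Tuple[CurieId, ...] = ()
    subsets: List[str] = field(default_factory=list)
    is_obsolete: bool = False
    opaque_lines: List[str] = field(default_factory=list)

    @property
    def is_anonymous_pattern(self) -> bool:
        return ANONYMOUS_PATTERN_SUBSET in self.subsets

    def referenced_ids(self) -> Tuple[CurieId, ...]:
        out: List[CurieId] = list(self.is_a)
        out.extend(t for _, t in self.relationships)
        out.extend(self.union_operands)
        if self.definition_expression is not None:
            out.extend(self.definition_expression.fillers())
        return tuple(out)


@dataclass
class Typedef:
    """One ``[Typedef]`` stanza (relation declaration); kept mostly opaque."""

    id: str
    name: Optional[str] = None
    opaque_lines: List[str] = field(default_factory=list)


@dataclass
class OntologyDocument:
    terms: List[OntologyTerm] = field(default_factory=list)
    typedefs: List[Typedef] = field(default_factory=list)
    header_lines: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: Dict[CurieId, OntologyTerm] = {}
        for t in self.terms:
            if t.id in self._index:
                raise DuplicateTermError(t.id.obo)
            self._index[t.id] = t

    def __eq__(self, other) -> bool:  # index is derived state, exclude it
        if not isinstance(other, OntologyDocument):
            return NotImplemented
        return (
            self.terms == other.terms
            and self.typedefs == other.typedefs
            and self.header_lines == other.header_lines
        )

    def get(self, term_id: CurieId) -> Optional[OntologyTerm]:
        return self._index.get(term_id)

    def __contains__(self, term_id: CurieId) -> bool:
        return term_id in self._index

    def add(self, term: OntologyTerm) -> None:
        if term.id in self._index:
            raise DuplicateTermError(term.id.obo)
        self.terms.append(term)
        self._index[term.id] = term

    def named_terms(self) -> List[OntologyTerm]:
        """Terms that are curation targets (not anonymous union operands)."""
        return [t for t in self.terms if not t.is_anonymous_pattern]

    def asserted_edges(self) -> Tuple[Tuple[CurieId, CurieId], ...]:
        """All asserted (child, parent) is_a pairs, id-sorted."""
        edges = []
        for t in self.terms:
            for p in t.is_a:
                edges.append((t.id, p))
        return tuple(sorted(edges))

    def term_graph(self):
        """The asserted is_a backbone as a :class:`~flypheno.graph.TermGraph`
        (dangling parents become leafless nodes)."""
        from .graph import TermGraph

        return TermGraph.from_edges(self.asserted_edges(), nodes=(t.id for t in self.terms))

    def dangling_references(self, imports: Iterable["OntologyDocument"] = ()) -> Tuple[CurieId, ...]:
        """Ids referenced by any term but resolvable neither locally nor in
        the supplied import documents."""
        known = set(self._index)
        for doc in imports:
            known |= set(doc._index)
        missing = set()
        for t in self.terms:
            for ref in t.referenced_ids():
                if ref not in known and ref != ABNORMAL:
                    missing.add(ref)
        return tuple(sorted(missing))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_DEF_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(?:\[(.*)\])?\s*$')


def _unescape(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def _strip_comment(value: str) -> str:
    # trailing " ! label" comments on id-valued lines
    idx = value.find(" ! ")
    if idx >= 0:
        value = value[:idx]
    return value.strip()


def parse_obo(text: str) -> OntologyDocument:
    """Parse OBO 1.4 text into an :class:`OntologyDocument`.

    Raises :class:`DuplicateTermError` for repeated stanza ids and
    :class:`PatternError` for malformed intersection_of blocks (exactly one
    genus line is required).
    """
    doc = OntologyDocument()
    lines = text.splitlines()
    i = 0
    n = len(lines)
    # header: everything before the first stanza
    while i < n and not lines[i].startswith("["):
        line = lines[i].rstrip()
        if line and not line.startswith("!"):
            if line.startswith("format-version:"):
                pass  # regenerated on write
            else:
                doc.header_lines.append(line)
        i += 1
    while i < n:
        stanza_type = lines[i].strip()
        i += 1
        body: List[str] = []
        while i < n and not lines[i].startswith("["):
            line = lines[i].rstrip()
            if line and not line.startswith("!"):
                body.append(line)
            i += 1
        if stanza_type == "[Term]":
            doc.add(_parse_term(body))
        elif stanza_type == "[Typedef]":
            doc.typedefs.append(_parse_typedef(body))
        else:
            raise OboParseError(f"unsupported stanza type: {stanza_type}")
    _resolve_unions(doc)
    return doc


def _tag_value(line: str) -> Tuple[str, str]:
    if ":" not in line:
        raise OboParseError(f"malformed tag line: {line!r}")
    tag, value = line.split(":", 1)
    return tag.strip(), value.strip()


def _parse_eq_lines(pairs: Sequence[Tuple[Optional[str], CurieId]], term_id: str, equivalence: bool) -> EQDefinition:
    genus = [f for rel, f in pairs if rel is None]
    if len(genus) != 1:
        raise PatternError(
            f"{term_id}: pattern requires exactly one genus line, found {len(genus)}"
        )
    quality = genus[0]
    entity = towards = None
    abnormal = False
    for rel, filler in pairs:
        if rel is None:
            continue
        if rel == INHERES_IN:
            if entity is not None:
                raise PatternError(f"{term_id}: more than one inheres_in filler")
            entity = filler
        elif rel == QUALIFIER:
            if filler != ABNORMAL:
                raise PatternError(f"{term_id}: unsupported qualifier filler {filler.obo}")
            abnormal = True
        elif rel == TOWARDS:
            if towards is not None:
                raise PatternError(f"{term_id}: more than one towards filler")
            towards = filler
        else:
            raise PatternError(f"{term_id}: unsupported pattern relation {rel!r}")
    return EQDefinition(
        quality=quality, entity=entity, towards=towards, abnormal=abnormal, equivalence=equivalence
    )


def _parse_term(body: List[str]) -> OntologyTerm:
    term_id: Optional[CurieId] = None
    fields: dict = {}
    eq_pairs: List[Tuple[Optional[str], CurieId]] = []
    nec_pairs: List[Tuple[Optional[str], CurieId]] = []
    is_a: List[CurieId] = []
    relationships: List[Tuple[str, CurieId]] = []
    subsets: List[str] = []
    union_operands: Tuple[CurieId, ...] = ()
    opaque: List[str] = []
    for line in body:
        tag, value = _tag_value(line)
        if tag == "id":
            term_id = CurieId.parse(_strip_comment(value))
        elif tag == "name":
            fields["label"] = value
        elif tag == "namespace":
            fields["namespace"] = _strip_comment(value)
        elif tag == "def":
            m = _DEF_RE.match(value)
            if m is None:
                raise OboParseError(f"malformed def line: {line!r}")
            fields["textual_definition"] = _unescape(m.group(1))
            xrefs = m.group(2)
            if xrefs:
                fields["definition_xrefs"] = tuple(
                    x.strip() for x in xrefs.split(",") if x.strip()
                )
        elif tag == "subset":
            subsets.append(_strip_comment(value))
        elif tag == "is_a":
            is_a.append(CurieId.parse(_strip_comment(value)))
        elif tag in ("intersection_of", NECESSARY_TAG):
            parts = _strip_comment(value).split()
            if len(parts) == 1:
                pair = (None, CurieId.parse(parts[0]))
            elif len(parts) == 2:
                pair = (parts[0], CurieId.parse(parts[1]))
            else:
                raise OboParseError(f"malformed {tag} line: {line!r}")
            (eq_pairs if tag == "intersection_of" else nec_pairs).append(pair)
        elif tag == UNION_TAG:
            union_operands = tuple(CurieId.parse(p) for p in _strip_comment(value).split())
        elif tag == "relationship":
            parts = _strip_comment(value).split()
            if len(parts) != 2:
                raise OboParseError(f"malformed relationship line: {line!r}")
            relationships.append((parts[0], CurieId.parse(parts[1])))
        elif tag == "is_obsolete":
            fields["is_obsolete"] = _strip_comment(value) == "true"
        else:
            opaque.append(line)
    if term_id is None:
        raise OboParseError("term stanza without an id")
    term = OntologyTerm(
        id=term_id,
        is_a=is_a,
        relationships=relationships,
        subsets=subsets,
        union_operands=union_operands,
        opaque_lines=opaque,
        **fields,
    )
    if eq_pairs and nec_pairs:
        raise PatternError(f"{term_id.obo}: a term has at most one definition expression")
    if eq_pairs:
        term.definition_expression = _parse_eq_lines(eq_pairs, term_id.obo, equivalence=True)
    elif nec_pairs:
        term.definition_expression = _parse_eq_lines(nec_pairs, term_id.obo, equivalence=False)
    if term.is_obsolete and (term.is_a or term.definition_expression or term.union_operands):
        raise OboParseError(f"{term_id.obo}: obsolete terms carry no parents or expression")
    return term


def _parse_typedef(body: List[str]) -> Typedef:
    td_id: Optional[str] = None
    name: Optional[str] = None
    opaque: List[str] = []
    for line in body:
        tag, value = _tag_value(line)
        if tag == "id":
            td_id = _strip_comment(value)
        elif tag == "name":
            name = value
        else:
            opaque.append(line)
    if td_id is None:
        raise OboParseError("typedef stanza without an id")
    return Typedef(id=td_id, name=name, opaque_lines=opaque)


def _resolve_unions(doc: OntologyDocument) -> None:
    """Turn ``equivalent_union_of`` operand lists into union EQDefinitions by
    pulling in the operand stanzas' own patterns."""
    for term in doc.terms:
        if not term.union_operands:
            continue
        if term.definition_expression is not None:
            raise PatternError(f"{term.id.obo}: a term has at most one definition expression")
        operands: List[EQDefinition] = []
        missing: List[CurieId] = []
        for op_id in term.union_operands:
            op = doc.get(op_id)
            if op is None or op.definition_expression is None:
                missing.append(op_id)
                continue
            operands.append(op.definition_expression)
        if missing:
            raise DanglingReferenceError([m.obo for m in missing])
        term.definition_expression = EQDefinition(operands=tuple(operands), equivalence=True)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_obo(doc: OntologyDocument, flavour: str = "full", hierarchy=None) -> str:
    """Serialise a document deterministically.

    ``flavour="full"`` reproduces pattern definitions (and the custom union /
    necessary-pattern tags).  ``flavour="simple"`` emits the pre-reasoned
    release: every structural line is an is_a link taken from ``hierarchy``
    (an :class:`~flypheno.classify.InferredHierarchy` or an iterable of
    (child, parent) pairs), and all pattern machinery — intersection_of,
    custom tags, anonymous operand stanzas, non-is_a relationships — is
    dropped.
    """
    if flavour not in ("full", "simple"):
        raise ValueError(f"unknown flavour: {flavour!r}")
    edges_by_child: Dict[CurieId, List[CurieId]] = {}
    if flavour == "simple":
        if hierarchy is None:
            raise ValueError("flavour='simple' requires a hierarchy")
        edges = getattr(hierarchy, "direct_edges", hierarchy)
        unknown = sorted({n.obo for e in edges for n in e if n not in doc})
        if unknown:
            raise DanglingReferenceError(unknown)
        for child, parent in sorted(edges):
            edges_by_child.setdefault(child, []).append(parent)

    out: List[str] = ["format-version: 1.4"]
    out.extend(_registration_lines(doc, flavour))
    for line in doc.header_lines:
        if line.startswith("subsetdef:") and any(
            line.startswith(f"subsetdef: {name} ") for name in _REGISTRATIONS
        ):
            continue  # regenerated above
        out.append(line)

    label_of = {t.id: t.label for t in doc.terms}

    def ref(i: CurieId) -> str:
        label = label_of.get(i)
        return f"{i.obo} ! {label}" if label else i.obo

    for term in sorted(doc.terms, key=lambda t: t.id):
        if flavour == "simple" and term.is_anonymous_pattern:
            continue
        out.append("")
        out.append("[Term]")
        out.append(f"id: {term.id.obo}")
        if term.label is not None:
            out.append(f"name: {term.label}")
        if term.namespace is not None:
            out.append(f"namespace: {term.namespace}")
        if term.textual_definition is not None:
            xrefs = ", ".join(term.definition_xrefs)
            out.append(f'def: "{_escape(term.textual_definition)}" [{xrefs}]')
        if flavour == "full":
            for s in sorted(term.subsets):
                out.append(f"subset: {s}")
            for p in sorted(term.is_a):
                out.append(f"is_a: {ref(p)}")
            expr = term.definition_expression
            if term.union_operands:
                ops = " ".join(i.obo for i in term.union_operands)
                out.append(f"{UNION_TAG}: {ops}")
            elif expr is not None:
                tag = "intersection_of" if expr.equivalence else NECESSARY_TAG
                out.extend(_eq_lines(tag, expr, ref))
            for rel, target in sorted(term.relationships):
                out.append(f"relationship: {rel} {ref(target)}")
            if term.is_obsolete:
                out.append("is_obsolete: true")
            out.extend(term.opaque_lines)
        else:
            for p in edges_by_child.get(term.id, []):
                out.append(f"is_a: {ref(p)}")
            if term.is_obsolete:
                out.append("is_obsolete: true")
    if flavour == "full":
        for td in sorted(doc.typedefs, key=lambda t: t.id):
            out.append("")
            out.append("[Typedef]")
            out.append(f"id: {td.id}")
            if td.name is not None:
                out.append(f"name: {td.name}")
            out.extend(td.opaque_lines)
    return "\n".join(out) + "\n"


def _eq_lines(tag: str, expr: EQDefinition, ref) -> List[str]:
    lines = [f"{tag}: {ref(expr.quality)}"]
    if expr.entity is not None:
        lines.append(f"{tag}: {INHERES_IN} {ref(expr.entity)}")
    if expr.abnormal:
        lines.append(f"{tag}: {QUALIFIER} {ABNORMAL.obo}")
    if expr.towards is not None:
        lines.append(f"{tag}: {TOWARDS} {ref(expr.towards)}")
    return lines


def _registration_lines(doc: OntologyDocument, flavour: str) -> List[str]:
    if flavour == "simple":
        return []
    used = []
    if any(t.is_anonymous_pattern for t in doc.terms):
        used.append(ANONYMOUS_PATTERN_SUBSET)
    if any(t.union_operands for t in doc.terms):
        used.append(UNION_TAG)
    if any(
        t.definition_expression is not None
        and not t.definition_expression.equivalence
        for t in doc.terms
    ):
        used.append(NECESSARY_TAG)
    return [_REGISTRATIONS[name] for name in used]
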