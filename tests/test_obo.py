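"""OBO parsing and writing: round-trips, pattern extraction, flavours."""

import pytest

from flypheno import (
    CurieId,
    DanglingReferenceError,
    DuplicateTermError,
    EQDefinition,
    PatternError,
    parse_obo,
    write_obo,
)
from flypheno.obo import OboParseError

from hypothesis import given, strategies as st


RADIATION_RESISTANT = """\
format-version: 1.4

[Term]
id: FBcv:0000439
name: radiation resistant
intersection_of: PATO:0001552
intersection_of: inheres_in GO:0009314
"""


def test_intersection_of_yields_eq_definition():
    doc = parse_obo(RADIATION_RESISTANT)
    term = doc.get(CurieId.parse("FBcv:0000439"))
    assert term.definition_expression == EQDefinition(
        quality=CurieId("PATO", "0001552"),
        entity=CurieId("GO", "0009314"),
        equivalence=True,
    )


def test_empty_document_parses_to_zero_terms():
    doc = parse_obo("format-version: 1.4\nontology: test\n")
    assert doc.terms == []
    assert doc.header_lines == ["ontology: test"]


def test_duplicate_stanza_id_is_a_structured_error():
    text = RADIATION_RESISTANT + "\n[Term]\nid: FBcv:0000439\nname: again\n"
    with pytest.raises(DuplicateTermError) as err:
        parse_obo(text)
    assert "FBcv:0000439" in str(err.value)


@pytest.mark.parametrize(
    "lines",
    [
        # zero genus lines
        ["intersection_of: inheres_in GO:0009314"],
        # two genus lines
        ["intersection_of: PATO:0001552", "intersection_of: PATO:0000001"],
    ],
)
def test_malformed_intersection_arity_is_a_pattern_error(lines):
    text = "format-version: 1.4\n\n[Term]\nid: FBcv:0000439\n" + "\n".join(lines) + "\n"
    with pytest.raises(PatternError):
        parse_obo(text)


def test_obsolete_terms_carry_no_parents():
    text = (
        "format-version: 1.4\n\n[Term]\nid: FBcv:0000001\nis_a: FBcv:0000002\n"
        "is_obsolete: true\n"
    )
    with pytest.raises(OboParseError):
        parse_obo(text)


def test_unknown_tags_round_trip_as_opaque_lines():
    text = (
        "format-version: 1.4\n\n[Term]\nid: FBcv:0000439\nname: radiation resistant\n"
        "xref: FlyBase:FBcv0000439\ncomment: kept verbatim\n"
    )
    doc = parse_obo(text)
    term = doc.terms[0]
    assert term.opaque_lines == ["xref: FlyBase:FBcv0000439", "comment: kept verbatim"]
    assert "comment: kept verbatim" in write_obo(doc)


@pytest.mark.parametrize(
    "name", ["mini-pato", "mini-go", "mini-cl", "mini-fbbt", "stage-ontology", "mini-dpo"]
)
def test_parse_write_parse_is_a_fixed_point(named_docs, name):
    """One write normalises; after that, parse/write cycles are stable."""
    doc = named_docs[name]
    text1 = write_obo(doc)
    doc2 = parse_obo(text1)
    text2 = write_obo(doc2)
    assert text1 == text2
    assert parse_obo(text2) == doc2


def test_two_writes_are_byte_identical(dpo, dpo_hierarchy):
    assert write_obo(dpo) == write_obo(dpo)
    a = write_obo(dpo, flavour="simple", hierarchy=dpo_hierarchy)
    b = write_obo(dpo, flavour="simple", hierarchy=dpo_hierarchy)
    assert a == b


def test_union_definition_round_trips(dpo):
    reparsed = parse_obo(write_obo(dpo))
    cdd = reparsed.get(CurieId.parse("FBcv:0000425"))
    assert cdd.definition_expression.is_union
    assert len(cdd.definition_expression.operands) == 2
    # custom tags are registered in the header
    header = "\n".join(l for l in write_obo(dpo).splitlines() if l.startswith("subsetdef"))
    assert "equivalent_union_of" in header
    assert "anonymous_pattern" in header


def test_simple_flavour_emits_only_inferred_is_a(dpo, dpo_hierarchy):
    text = write_obo(dpo, flavour="simple", hierarchy=dpo_hierarchy)
    structural = [
        l for l in text.splitlines()
        if l.split(":")[0] in ("intersection_of", "relationship", "equivalent_union_of",
                               "necessary_pattern", "subset")
    ]
    assert structural == []
    doc = parse_obo(text)
    assert set(doc.asserted_edges()) == set(dpo_hierarchy.direct_edges)


def test_simple_flavour_with_asserted_hierarchy_reproduces_asserted(named_docs):
    go = named_docs["mini-go"]
    text = write_obo(go, flavour="simple", hierarchy=go.asserted_edges())
    assert set(parse_obo(text).asserted_edges()) == set(go.asserted_edges())


def test_simple_flavour_requires_hierarchy(dpo):
    with pytest.raises(ValueError):
        write_obo(dpo, flavour="simple")


def test_simple_flavour_rejects_foreign_hierarchy_ids(dpo):
    bad = [(CurieId("FBcv", "0000408"), CurieId("XX", "9999999"))]
    with pytest.raises(DanglingReferenceError) as err:
        write_obo(dpo, flavour="simple", hierarchy=bad)
    assert "XX:9999999" in str(err.value)


def test_dangling_references_are_reported_not_fatal(named_docs):
    dpo = named_docs["mini-dpo"]
    missing = dpo.dangling_references()
    # without imports loaded, the GO/PATO/CL/FBbt fillers dangle
    assert CurieId("GO", "0006950") in missing
    assert dpo.dangling_references(named_docs.values()) == ()


def test_obonet_reads_the_full_flavour(dpo):
    """Cross-check with an independent OBO reader: same named terms, same
    is_a backbone, custom tags skipped safely."""
    import io
    import obonet

    graph = obonet.read_obo(io.StringIO(write_obo(dpo)), ignore_obsolete=False)
    ours = {t.id.obo for t in dpo.terms}
    assert set(graph.nodes) == ours
    theirs = {
        (c, p) for c, p, k in graph.edges(keys=True) if k == "is_a"
    }
    assert theirs == {(c.obo, p.obo) for c, p in dpo.asserted_edges()}


@given(
    prefix=st.sampled_from(["GO", "PATO", "FBcv", "CL", "FBbt"]),
    local=st.integers(min_value=0, max_value=9_999_999),
)
def test_curie_spellings_round_trip(prefix, local):
    cid = CurieId(prefix, f"{local:07d}")
    assert CurieId.parse(cid.obo) == cid
    assert CurieId.parse(cid.short_form) == cid
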