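"""Structural subsumption and document classification."""

import random

import pytest

from flypheno import (
    CurieId,
    CycleError,
    EQDefinition,
    UnknownTermError,
    classify,
    eq_subsumes,
    inference_stats,
)
from flypheno.classify import ASSERTED, INFERRED, InferenceStats
from flypheno.eq import PHENOTYPE_ROOT_DEFINITION, QUALITY
from flypheno.fixtures import (
    FixtureSpec,
    fbcv_id,
    go_id,
    random_instance,
)
from flypheno.graph import TermGraph
from flypheno.obo import OntologyDocument, OntologyTerm, parse_obo, write_obo

from _oracles import homomorphism_subsumes


def _def_of(doc, label):
    return doc.get(fbcv_id(label)).definition_expression


def test_subsumption_is_reflexive(dpo, imports):
    for term in dpo.terms:
        d = term.definition_expression
        if d is not None:
            assert eq_subsumes(d, d, imports)


def test_cold_stress_response_under_both_groupings(dpo, imports):
    cold = _def_of(dpo, "cold stress response defective")
    assert eq_subsumes(cold, _def_of(dpo, "stress response defective"), imports)
    assert eq_subsumes(cold, _def_of(dpo, "temperature response defective"), imports)


def test_membership_in_a_union_via_one_operand(dpo, imports):
    pcd_defect = EQDefinition(
        quality=QUALITY, entity=go_id("programmed cell death"), abnormal=True
    )
    union = _def_of(dpo, "cell death defective")
    assert union.is_union
    assert eq_subsumes(pcd_defect, union, imports)
    # the union is below the phenotype root because both operands are
    assert eq_subsumes(union, PHENOTYPE_ROOT_DEFINITION, imports)


def test_unresolved_filler_is_an_error_not_false(imports):
    broken = EQDefinition(quality=QUALITY, entity=CurieId("GO", "7777777"), abnormal=True)
    good = EQDefinition(quality=QUALITY, entity=go_id("behavior"), abnormal=True)
    with pytest.raises(UnknownTermError):
        eq_subsumes(broken, good, imports)


def test_every_abnormal_definition_is_under_the_phenotype_root(dpo, imports, dpo_hierarchy):
    root = fbcv_id("phenotype")
    for term in dpo.named_terms():
        d = term.definition_expression
        if d is None or term.id == root:
            continue
        flags = [d.abnormal] if not d.is_union else [op.abnormal for op in d.operands]
        if all(flags):
            assert eq_subsumes(d, PHENOTYPE_ROOT_DEFINITION, imports)
            assert root in dpo_hierarchy.superclasses_of(term.id)


def test_necessary_only_definitions_attract_no_descendants(dpo, imports, dpo_hierarchy):
    jumping = fbcv_id("jumping defective")
    jump_response = fbcv_id("jump response defective")
    # the equivalence-defined term is not pulled under the necessary-only one
    assert jumping not in dpo_hierarchy.superclasses_of(jump_response)
    assert dpo_hierarchy.subclasses_of(jumping) == frozenset()
    # and the necessary-only term stays neutral about behavior
    assert fbcv_id("behavior defective") not in dpo_hierarchy.superclasses_of(jumping)


def test_single_term_document_has_no_inferred_edges(imports):
    doc = OntologyDocument()
    doc.add(OntologyTerm(
        id=fbcv_id("behavior defective"), label="behavior defective",
        definition_expression=EQDefinition(quality=QUALITY, entity=go_id("behavior"), abnormal=True),
    ))
    h = classify(doc, imports)
    assert h.direct_edges == ()


def test_identical_definitions_yield_an_equivalence_group(imports):
    doc = OntologyDocument()
    d = EQDefinition(quality=QUALITY, entity=go_id("behavior"), abnormal=True)
    a, b = CurieId("FBcv", "0000101"), CurieId("FBcv", "0000102")
    doc.add(OntologyTerm(id=a, label="one", definition_expression=d))
    doc.add(OntologyTerm(id=b, label="two", definition_expression=d))
    h = classify(doc, imports)
    assert h.equivalence_groups == (frozenset({a, b}),)
    assert (a, b) in h.closure and (b, a) in h.closure


def test_cyclic_asserted_is_a_is_an_error(imports):
    doc = OntologyDocument()
    a, b = CurieId("FBcv", "0000101"), CurieId("FBcv", "0000102")
    doc.add(OntologyTerm(id=a, label="one", is_a=[b]))
    doc.add(OntologyTerm(id=b, label="two", is_a=[a]))
    with pytest.raises(CycleError):
        classify(doc, imports)


def test_provenance_separates_asserted_from_inferred(dpo, dpo_hierarchy):
    asserted = set(dpo.asserted_edges())
    for edge in dpo_hierarchy.direct_edges:
        expected = ASSERTED if edge in asserted else INFERRED
        assert dpo_hierarchy.provenance[edge] == expected
    # the legacy asserted subclass links survive reduction as asserted
    cold = (fbcv_id("cold stress response defective"), fbcv_id("stress response defective"))
    assert dpo_hierarchy.provenance[cold] == ASSERTED


def test_stats_use_half_up_percent_rounding():
    assert InferenceStats(n_direct=305, n_inferred=258).percent_inferred == 85
    assert InferenceStats(n_direct=200, n_inferred=1).percent_inferred == 1
    assert InferenceStats(n_direct=400, n_inferred=2).percent_inferred == 1  # 0.5 rounds up
    assert InferenceStats(n_direct=10, n_inferred=0).percent_inferred == 0


def test_stats_against_independent_set_difference(dpo, dpo_hierarchy):
    stats = inference_stats(dpo.term_graph(), dpo_hierarchy)
    oracle_inferred = set(dpo_hierarchy.direct_edges) - set(dpo.asserted_edges())
    assert stats.n_direct == len(dpo_hierarchy.direct_edges)
    assert stats.n_inferred == len(oracle_inferred)
    assert 0 < stats.n_inferred <= stats.n_direct


def test_classifying_a_simple_release_is_idempotent(dpo, dpo_hierarchy, imports):
    simple = parse_obo(write_obo(dpo, flavour="simple", hierarchy=dpo_hierarchy))
    again = classify(simple, imports)
    assert set(again.direct_edges) == set(dpo_hierarchy.direct_edges)
    assert inference_stats(simple.term_graph(), again).n_inferred == 0


def test_classification_is_monotone_under_import_growth(imports):
    doc, imp = random_instance(FixtureSpec(seed=11, n_terms=10))
    before = classify(doc, imp).closure
    # add one is_a edge between two previously unrelated entity nodes
    ent = imp["EX"]
    nodes = sorted(ent.nodes)
    extra = (nodes[-1], nodes[1])
    grown = dict(imp)
    grown["EX"] = TermGraph.from_edges(set(ent.edges) | {extra}, nodes=ent.nodes)
    after = classify(doc, grown).closure
    assert before <= after


@pytest.mark.parametrize("seed", range(25))
def test_eq_subsumes_matches_homomorphism_oracle_on_random_pairs(seed):
    doc, imp = random_instance(FixtureSpec(seed=seed, n_terms=10))
    defs = [t.definition_expression for t in doc.named_terms()
            if t.definition_expression is not None]
    rng = random.Random(seed)
    for _ in range(20):
        d1, d2 = rng.choice(defs), rng.choice(defs)
        assert eq_subsumes(d1, d2, imp) == homomorphism_subsumes(d1, d2, imp)
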