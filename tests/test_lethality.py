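"""Lethal-phase term generation, subsumption, model checking, annotation."""

import itertools

import pytest
from hypothesis import given, strategies as st

from flypheno import (
    CurieId,
    MortalityObservation,
    MortalityRange,
    Thresholds,
    annotate_mortality,
    classify_lethal,
    generate_lethal_phase_terms,
    lethal_subsumes,
    model_check_subsumption,
)
from flypheno.errors import FlyphenoError
from flypheno.fixtures import fbdv_id
from flypheno.lethality import (
    INCREASED_MORTALITY_ID,
    LETHAL_ID,
    PARTIALLY_LETHAL_ID,
    SHORT_LIVED_ID,
)
from flypheno.temporal import Stage, StageChain


def _chain(n: int) -> StageChain:
    return StageChain(tuple(Stage(CurieId("SX", f"{i:07d}"), f"stage {i}") for i in range(n)))


def _by_label(terms):
    return {t.label: t for t in terms}


# ---------------------------------------------------------------------------
# Mortality ranges
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,lo,hi",
    [
        (">=5", 5, 100),
        (">50, <= 98", 51, 98),
        ("short[>=98]", 98, 100),
        ("short[>50, <=98]", 51, 98),
        ("<5", 0, 4),
    ],
)
def test_printed_bounds_normalise_to_closed_integer_intervals(text, lo, hi):
    r = MortalityRange.from_text(text)
    assert (r.lo, r.hi) == (lo, hi)
    # normalisation round-trips losslessly over the integer datatype
    assert MortalityRange.from_text(r.to_text()) == r


def test_out_of_range_bounds_are_rejected():
    with pytest.raises(FlyphenoError):
        MortalityRange(50, 101)
    with pytest.raises(FlyphenoError):
        MortalityRange(60, 40)


@given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
def test_range_membership_matches_interval_arithmetic(lo, hi, x):
    if lo > hi:
        lo, hi = hi, lo
    r = MortalityRange(lo, hi)
    assert (x in r) == (lo <= x <= hi)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def test_four_stage_chain_yields_21_flat_terms(chain, lethal_terms):
    # 3 pre-adult stages x {some,most,all} x {during, before end of} + 3 core
    assert len(lethal_terms) == 21
    labels = {t.label for t in lethal_terms}
    assert "lethal" in labels
    assert "increased mortality" in labels
    assert "partially lethal - majority die" in labels
    assert "lethal - all die during embryonic stage" in labels
    assert "some die before end of pupal stage" in labels


def test_smallest_valid_chain_yields_9_terms():
    terms = generate_lethal_phase_terms(_chain(2))
    assert len(terms) == 9


def test_default_thresholds_reproduce_the_printed_bands(lethal_terms):
    by = _by_label(lethal_terms)
    assert by["increased mortality"].range == MortalityRange(5, 100)
    assert by["lethal"].range == MortalityRange(98, 100)
    assert by["partially lethal - majority die"].range == MortalityRange(51, 98)
    assert by["majority die during larval stage"].range == MortalityRange(50, 100)


def test_short_lived_is_opt_in(chain):
    default = {t.id for t in generate_lethal_phase_terms(chain)}
    assert SHORT_LIVED_ID not in default
    with_it = _by_label(generate_lethal_phase_terms(chain, include_short_lived=True))
    sl = with_it["short lived"]
    assert sl.id == SHORT_LIVED_ID
    assert sl.age.stage == chain.final_stage.id


def test_minted_ids_are_stable_across_runs(chain):
    a = generate_lethal_phase_terms(chain)
    b = generate_lethal_phase_terms(chain)
    assert a == b
    assert all(t.id.prefix == "LP" for t in a if t.id.prefix != "FBcv")


def test_bad_thresholds_are_rejected():
    with pytest.raises(FlyphenoError):
        Thresholds(some=0)
    with pytest.raises(FlyphenoError):
        Thresholds(some=60, most=50)


# ---------------------------------------------------------------------------
# Subsumption and classification
# ---------------------------------------------------------------------------


def test_all_die_during_first_stage_is_lethal(chain, lethal_terms):
    by = _by_label(lethal_terms)
    assert lethal_subsumes(by["lethal - all die during embryonic stage"], by["lethal"], chain)
    assert not lethal_subsumes(by["lethal"], by["lethal - all die during embryonic stage"], chain)


def test_partially_lethal_and_lethal_do_not_nest(chain, lethal_terms):
    by = _by_label(lethal_terms)
    pl, lethal = by["partially lethal - majority die"], by["lethal"]
    assert not lethal_subsumes(pl, lethal, chain)
    assert not lethal_subsumes(lethal, pl, chain)


def test_every_generated_term_shows_increased_mortality(chain, lethal_terms):
    by = _by_label(lethal_terms)
    for t in lethal_terms:
        assert lethal_subsumes(t, by["increased mortality"], chain)


def test_subsumption_is_a_preorder(chain, lethal_terms):
    for t in lethal_terms:
        assert lethal_subsumes(t, t, chain)
    for a, b, c in itertools.product(lethal_terms, repeat=3):
        if lethal_subsumes(a, b, chain) and lethal_subsumes(b, c, chain):
            assert lethal_subsumes(a, c, chain)


def test_flat_set_classifies_into_a_nested_dag(chain, lethal_terms):
    h = classify_lethal(lethal_terms, chain)
    assert len(h.direct_edges) >= len(lethal_terms) - 1
    # unique top element among generated terms
    reps = {c for c, _ in h.direct_edges} | {p for _, p in h.direct_edges}
    tops = reps - {c for c, _ in h.direct_edges}
    assert tops == {INCREASED_MORTALITY_ID}
    # lethal and 'all die before end of <last pre-adult stage>' coincide
    assert any(LETHAL_ID in g for g in h.equivalence_groups)


def test_single_term_input_has_no_edges(chain, lethal_terms):
    h = classify_lethal(lethal_terms[:1], chain)
    assert h.direct_edges == ()


def test_nesting_chain_from_first_stage_to_lethal(chain, lethal_terms):
    by = _by_label(lethal_terms)
    closure = classify_lethal(lethal_terms, chain).closure
    sequence = [
        by["lethal - all die during embryonic stage"],
        by["lethal - all die before end of embryonic stage"],
        by["lethal - all die before end of larval stage"],
        by["lethal - all die before end of pupal stage"],
        by["lethal"],
    ]
    for child, parent in zip(sequence, sequence[1:]):
        assert (child.id, parent.id) in closure or any(
            child.id in g and parent.id in g
            for g in classify_lethal(lethal_terms, chain).equivalence_groups
        )


def test_mismatched_chain_is_an_error(lethal_terms):
    other = _chain(3)
    with pytest.raises(FlyphenoError):
        lethal_subsumes(lethal_terms[0], lethal_terms[1], other)


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------


def test_total_embryonic_death_satisfies_lethal(chain, lethal_terms):
    from flypheno.lethality import _satisfies

    by = _by_label(lethal_terms)
    mass = (100, 0, 0, 0)
    assert _satisfies(mass, by["lethal"], chain)
    assert _satisfies(mass, by["lethal - all die during embryonic stage"], chain)


def test_three_quarters_mortality_is_partially_lethal_not_lethal(chain, lethal_terms):
    from flypheno.lethality import _satisfies

    by = _by_label(lethal_terms)
    mass = (50, 25, 0, 0)
    assert _satisfies(mass, by["partially lethal - majority die"], chain)
    assert not _satisfies(mass, by["lethal"], chain)


def test_model_checker_refutes_the_converse_direction(chain, lethal_terms):
    by = _by_label(lethal_terms)
    assert model_check_subsumption(
        by["lethal - all die during embryonic stage"], by["lethal"], chain
    )
    assert not model_check_subsumption(
        by["lethal"], by["lethal - all die during embryonic stage"], chain
    )


def test_population_sizes_are_bounded(chain, lethal_terms):
    with pytest.raises(FlyphenoError):
        model_check_subsumption(lethal_terms[0], lethal_terms[1], chain, population_sizes=[9])


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def _obs(emb, larv, pup):
    return MortalityObservation({
        fbdv_id("embryonic stage"): emb,
        fbdv_id("larval stage"): larv,
        fbdv_id("pupal stage"): pup,
    })


def test_total_embryonic_death_annotates_to_the_single_most_specific_term(
    chain, lethal_terms
):
    by = _by_label(lethal_terms)
    result = annotate_mortality(_obs(100, 0, 0), lethal_terms, chain)
    assert result == {by["lethal - all die during embryonic stage"].id}


def test_zero_mortality_annotates_to_nothing(chain, lethal_terms):
    assert annotate_mortality(_obs(0, 0, 0), lethal_terms, chain) == frozenset()


def test_split_mortality_includes_partially_lethal(chain, lethal_terms):
    result = annotate_mortality(_obs(30, 40, 0), lethal_terms, chain)
    assert PARTIALLY_LETHAL_ID in result


def test_annotation_output_is_an_antichain(chain, lethal_terms):
    by_id = {t.id: t for t in lethal_terms}
    for obs in (_obs(100, 0, 0), _obs(30, 40, 0), _obs(5, 0, 0), _obs(50, 0, 48)):
        result = annotate_mortality(obs, lethal_terms, chain)
        for a, b in itertools.permutations(result, 2):
            assert not lethal_subsumes(by_id[a], by_id[b], chain)


def test_observation_outside_percent_range_is_an_error():
    with pytest.raises(FlyphenoError):
        MortalityObservation({fbdv_id("embryonic stage"): 120})


def test_observation_must_cover_pre_adult_stages(chain, lethal_terms):
    partial = MortalityObservation({fbdv_id("embryonic stage"): 10})
    with pytest.raises(FlyphenoError):
        annotate_mortality(partial, lethal_terms, chain)


def test_observation_tsv_round_trip(chain):
    text = "# stage\tpercent\nFBdv:0005289\t30\nFBdv:0005336\t40\nFBdv:0005342\t0\n"
    obs = MortalityObservation.from_tsv(text)
    assert obs.mass_vector(chain) == (30, 40, 0, 0)
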