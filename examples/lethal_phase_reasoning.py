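"""Generate lethal-phase terms, classify them, and annotate an observation.

The term set is flat when generated: each term is just a mortality band
attached to an age window over the life-stage chain.  Classification nests
it into a DAG, and a per-stage mortality table is annotated with the most
specific applicable terms.
"""

from flypheno import (
    MortalityObservation,
    annotate_mortality,
    classify_lethal,
    generate_lethal_phase_terms,
)
from flypheno.fixtures import default_stage_chain, fbdv_id

chain = default_stage_chain()
terms = generate_lethal_phase_terms(chain)
by_id = {t.id: t for t in terms}
print(f"{len(terms)} flat terms over {len(chain)} stages "
      f"({', '.join(s.label for s in chain.stages)})")

hierarchy = classify_lethal(terms, chain)
print(f"after classification: {len(hierarchy.direct_edges)} direct edges, "
      f"{len(hierarchy.equivalence_groups)} equivalence group(s)")
lethal_children = sorted(
    by_id[c].label for c, p in hierarchy.direct_edges if by_id[p].label == "lethal"
)
print("direct children of 'lethal':", "; ".join(lethal_children))

obs = MortalityObservation({
    fbdv_id("embryonic stage"): 30,
    fbdv_id("larval stage"): 40,
    fbdv_id("pupal stage"): 0,
})
result = annotate_mortality(obs, terms, chain)
print("\nannotation for 30% embryonic + 40% larval increased mortality:")
for tid in sorted(result):
    print(f"  {tid.obo}  {by_id[tid].label}")
# 70% cumulative pre-adult mortality: a majority dies (partially lethal),
# with the per-stage terms pinning down where the deaths happen.
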