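"""Auto-classify pattern-defined phenotype terms against a process ontology.

Builds the bundled miniature phenotype ontology (EQ pattern definitions over
mini GO/PATO/CL/anatomy imports), runs the structural classifier and prints
the inferred placement of the stress-response fragment.
"""

from flypheno import classify, inference_stats
from flypheno.fixtures import default_imports, fbcv_id, make_mini_dpo

dpo = make_mini_dpo()
imports = default_imports()
hierarchy = classify(dpo, imports)
labels = {t.id: t.label for t in dpo.terms}

srd = fbcv_id("stress response defective")
print("subclasses of 'stress response defective':")
for sub in sorted(hierarchy.subclasses_of(srd)):
    print(f"  {sub.obo}  {labels[sub]}")

cold = fbcv_id("cold stress response defective")
print("\nsuperclasses of 'cold stress response defective':")
for sup in sorted(hierarchy.superclasses_of(cold)):
    print(f"  {sup.obo}  {labels[sup]}")

stats = inference_stats(dpo.term_graph(), hierarchy)
print(
    f"\n{stats.n_direct} direct classifications, {stats.n_inferred} inferred "
    f"({stats.percent_inferred}%)."
)
# The classifier leverages the process ontology's structure: 'cold stress
# response defective' sits under both the stress and temperature groupings
# without either link being asserted by hand.
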