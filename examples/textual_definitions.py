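"""Derive human-readable definitions for process phenotypes automatically.

For terms defined with the plain 'abnormal quality of a GO process' pattern
and lacking a manual definition, a textual definition is generated from the
GO term's label and definition, so it tracks the GO as it changes.
"""

from flypheno import roll_textual_definitions
from flypheno.fixtures import fbcv_id, make_mini_dpo, make_mini_go

dpo = make_mini_dpo()
go = make_mini_go()
go_terms = {t.id: (t.label, t.textual_definition or "") for t in go.terms}

updated = roll_textual_definitions(dpo, go_terms)
print(f"updated {len(updated)} term(s): {', '.join(i.obo for i in updated)}\n")
term = dpo.get(fbcv_id("stress response defective"))
print(term.textual_definition)
# Only this term is touched: the others either carry manual definitions, use
# a more specific quality genus, or their GO filler has no definition in the
# miniature import.
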