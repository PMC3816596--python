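"""Exception hierarchy for the toolkit.

Every error that names an ontology entity carries the offending id so that
pipeline logs and findings files can point curators at the right term.
"""

from __future__ import annotations


class FlyphenoError(Exception):
    """Base class for all toolkit errors."""


class OboParseError(FlyphenoError):
    """Raised for syntactically or structurally invalid OBO input."""


class DuplicateTermError(OboParseError):
    def __init__(self, term_id: str):
        self.term_id = term_id
        super().__init__(f"duplicate stanza id: {term_id}")


class PatternError(FlyphenoError):
    """An entity-quality pattern is malformed (e.g. wrong genus arity)."""


class DanglingReferenceError(FlyphenoError):
    def __init__(self, ids):
        self.ids = tuple(ids)
        listed = ", ".join(str(i) for i in self.ids)
        super().__init__(f"unresolved references: {listed}")


class UnknownTermError(FlyphenoError):
    def __init__(self, term_id, context: str = ""):
        self.term_id = term_id
        msg = f"unknown term: {term_id}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class CycleError(FlyphenoError):
    def __init__(self, cycle):
        self.cycle = tuple(cycle)
        shown = " -> ".join(str(n) for n in self.cycle)
        super().__init__(f"cycle detected: {shown}")
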