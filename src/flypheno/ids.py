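"""Prefixed ontology identifiers (CURIEs).

Terms from OBO-library ontologies are identified by a namespace prefix and a
zero-padded numeric local part.  Two spellings are in circulation: the OBO
form ``GO:0006950`` used inside ``.obo`` files, and the OWL short form
``GO_0006950`` used in short-form URIs (prepend ``http://purl.obolibrary.org/
obo/`` to obtain the full IRI).  The two render losslessly into each other by
swapping the separator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)[:_]([A-Za-z0-9][A-Za-z0-9.-]*)$")


@dataclass(frozen=True, order=True)
class CurieId:
    """A prefixed identifier such as ``FBcv:0000408``.

    ``prefix`` is the namespace token (``GO``, ``PATO``, ``FBcv`` ...) and
    ``local`` the (usually zero-padded numeric) local part.  Instances are
    immutable, hashable and ordered lexicographically, which gives every
    iteration in the toolkit a reproducible order.
    """

    prefix: str
    local: str

    @classmethod
    def parse(cls, text: str) -> "CurieId":
        """Parse either the OBO form (``GO:0006950``) or short form
        (``GO_0006950``)."""
        m = _CURIE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a prefixed identifier: {text!r}")
        return cls(m.group(1), m.group(2))

    @property
    def obo(self) -> str:
        """OBO-file spelling, ``prefix:local``."""
        return f"{self.prefix}:{self.local}"

    @property
    def short_form(self) -> str:
        """OWL short-form spelling, ``prefix_local``."""
        return f"{self.prefix}_{self.local}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.obo
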