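"""The desk-scale release pipeline.

Mirrors a continuous-integration ontology release at desk scale: validate
the pattern definitions, extract paths-to-root modules from the imports,
classify, roll automated textual definitions, and emit

* ``<name>-full.obo``   — patterns intact, auto-text rolled in;
* ``<name>-simple.obo`` — the pre-reasoned flavour: inferred, transitively
  reduced is_a links only;
* ``stats.tsv``         — asserted-vs-inferred classification statistics;
* ``edges.tsv``         — the direct edge list with per-edge provenance;
* ``findings.tsv``      — validation findings (dangling references,
  pattern findings, inferred equivalences);
* optionally ``lethal.obo`` / ``lethal-edges.tsv`` — the generated
  lethal-phase term set and its classified hierarchy.

Exit status: 0 on success, 1 when strict validation fails, 2 on I/O
failure.  Running the pipeline twice on identical inputs produces
byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

from .classify import InferredHierarchy, classify, inference_stats
from .eq import Finding, roll_textual_definitions, validate_definition
from .errors import FlyphenoError
from .fixtures import make_named_fixtures
from .graph import TermGraph
from .ids import CurieId
from .lethality import (
    Thresholds,
    classify_lethal,
    generate_lethal_phase_terms,
)
from .obo import OntologyDocument, OntologyTerm, parse_obo, write_obo
from .temporal import StageChain

log = logging.getLogger("flypheno.release")


@dataclass
class ReleaseConfig:
    ontology: Path
    imports: Dict[str, Path] = field(default_factory=dict)
    out_dir: Path = Path("release")
    name: Optional[str] = None
    strict: bool = False
    generate_lethal: bool = False
    stage_ontology: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    with_short_lived: bool = False

    def __post_init__(self) -> None:
        self.ontology = Path(self.ontology)
        self.out_dir = Path(self.out_dir)
        self.imports = {k: Path(v) for k, v in self.imports.items()}
        if self.name is None:
            self.name = self.ontology.stem


@dataclass
class ReleaseResult:
    exit_code: int
    artifacts: Dict[str, Path] = field(default_factory=dict)
    findings: List[Finding] = field(default_factory=list)
    stats: Optional[object] = None
    hierarchy: Optional[InferredHierarchy] = None


def _load(path: Path) -> OntologyDocument:
    return parse_obo(path.read_text())


def collect_findings(
    doc: OntologyDocument,
    import_docs: Mapping[str, OntologyDocument],
    graphs: Mapping[str, TermGraph],
) -> List[Finding]:
    findings: List[Finding] = []
    for ref in doc.dangling_references(import_docs.values()):
        findings.append(Finding("dangling-reference", ref.obo, "referenced id does not resolve"))
    for term in doc.named_terms():
        if term.definition_expression is not None:
            findings.extend(validate_definition(term.definition_expression, graphs, term.id.obo))
    return findings


def run_release(config: ReleaseConfig) -> ReleaseResult:
    """Run the full pipeline; see module docstring for the artifact set."""
    result = ReleaseResult(exit_code=0)
    try:
        doc = _load(config.ontology)
        import_docs = {p: _load(path) for p, path in sorted(config.imports.items())}
    except (OSError, FlyphenoError) as exc:
        log.error("failed to read inputs: %s", exc)
        return ReleaseResult(exit_code=2)

    graphs: Dict[str, TermGraph] = {}
    for prefix, idoc in import_docs.items():
        graphs[prefix] = idoc.term_graph()

    findings = collect_findings(doc, import_docs, graphs)
    result.findings = findings

    hard = [f for f in findings if f.code in ("dangling-reference", "unresolved-filler")]
    if hard:
        for f in hard:
            log.warning("%s: %s (%s)", f.code, f.subject, f.message)

    try:
        config.out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - filesystem failure
        log.error("cannot create output directory: %s", exc)
        return ReleaseResult(exit_code=2)

    if hard and config.strict:
        _write_findings(config, result, findings)
        result.exit_code = 1
        return result

    # roll automated textual definitions from the process-ontology import
    go_terms: Dict[CurieId, Tuple[str, str]] = {}
    for idoc in import_docs.values():
        for t in idoc.terms:
            if t.id.prefix == "GO" and t.label:
                go_terms[t.id] = (t.label, t.textual_definition or "")
    rolled = roll_textual_definitions(doc, go_terms)
    if rolled:
        log.info("rolled %d automated textual definitions", len(rolled))

    hierarchy = classify(doc, graphs)
    result.hierarchy = hierarchy
    for group in hierarchy.equivalence_groups:
        ids = ", ".join(i.obo for i in sorted(group))
        findings.append(Finding("inferred-equivalence", min(group).obo,
                                f"terms inferred mutually equivalent: {ids}"))
        log.warning("inferred equivalence: %s", ids)

    stats = inference_stats(doc.term_graph(), hierarchy)
    result.stats = stats

    name = config.name
    out = config.out_dir
    artifacts = {
        "full": out / f"{name}-full.obo",
        "simple": out / f"{name}-simple.obo",
        "stats": out / "stats.tsv",
        "edges": out / "edges.tsv",
    }
    artifacts["full"].write_text(write_obo(doc, flavour="full"))
    artifacts["simple"].write_text(write_obo(doc, flavour="simple", hierarchy=hierarchy))
    artifacts["stats"].write_text("\n".join(stats.rows()) + "\n")
    artifacts["edges"].write_text("\n".join(hierarchy.edge_rows()) + "\n")

    if config.generate_lethal:
        try:
            stage_doc = (
                _load(config.stage_ontology)
                if config.stage_ontology is not None
                else make_named_fixtures()["stage-ontology"]
            )
            chain = StageChain.from_obo_document(stage_doc)
        except (OSError, FlyphenoError) as exc:
            log.error("cannot load stage chain: %s", exc)
            return ReleaseResult(exit_code=2, findings=findings)
        terms = generate_lethal_phase_terms(
            chain, config.thresholds, include_short_lived=config.with_short_lived
        )
        lethal_hierarchy = classify_lethal(terms, chain)
        artifacts["lethal"] = out / "lethal.obo"
        artifacts["lethal-edges"] = out / "lethal-edges.tsv"
        artifacts["lethal"].write_text(write_obo(lethal_terms_document(terms, chain)))
        artifacts["lethal-edges"].write_text("\n".join(lethal_hierarchy.edge_rows()) + "\n")

    result.artifacts = artifacts
    _write_findings(config, result, findings)
    return result


def _write_findings(config: ReleaseConfig, result: ReleaseResult, findings: List[Finding]) -> None:
    path = config.out_dir / "findings.tsv"
    rows = ["code\tsubject\tmessage"] + [f.as_tsv_row() for f in findings]
    path.write_text("\n".join(rows) + "\n")
    result.artifacts["findings"] = path


def lethal_terms_document(terms, chain: StageChain) -> OntologyDocument:
    """Render generated lethal-phase terms as a flat OBO document (labels,
    textual band/age descriptions; no parent links)."""
    doc = OntologyDocument()
    for t in sorted(terms, key=lambda t: t.id):
        doc.add(OntologyTerm(
            id=t.id,
            label=t.label,
            namespace="fly_phenotype",
            textual_definition=(
                f"A phenotype of a population in which the increased mortality "
                f"rate {t.range.to_text()} percent applies to deaths "
                f"{t.age.describe(chain)}."
            ),
        ))
    return doc
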