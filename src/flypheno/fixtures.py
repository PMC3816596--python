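"""Miniature ontology fixtures and seeded random instances.

Nothing in this toolkit requires downloading real ontology releases: this
module generates self-contained miniature counterparts of the ontologies the
entity-quality patterns import —

* a mini quality ontology (PATO-style): quality, abnormal, the specific
  qualities the patterns use;
* a mini process ontology (GO-style) carrying the stress-response and
  behavior fragments that drive the worked auto-classification examples,
  including the dual parentage of 'response to cold' (under both 'response
  to stress' and 'response to temperature stimulus');
* mini cell (CL-style) and anatomy (FBbt-style) ontologies;
* a life-stage ontology whose stages chain via immediately_preceded_by;
* a mini phenotype ontology (FBcv-style) carrying the printed pattern
  definitions: processual and behavioral defects, cell phenotypes, a union
  definition for 'cell death defective' and a necessary-condition-only
  definition for 'jumping defective'.

The process-ontology fragment is transcribed here once and is the single
source of truth for the stress-response worked example (8 subclasses of
'stress response defective').  Seeded random instances (DAG imports plus
random EQ definitions) support property-based testing; generation is a pure
function of the spec.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .eq import EQDefinition
from .graph import TermGraph
from .ids import CurieId
from .obo import ANONYMOUS_PATTERN_SUBSET, OntologyDocument, OntologyTerm, Typedef, write_obo
from .temporal import StageChain

# --------------------------------------------------------------------------
# Well-known fixture ids
# --------------------------------------------------------------------------

GO = {
    "biological_process": "0008150",
    "response to stimulus": "0050896",
    "response to stress": "0006950",
    "response to abiotic stimulus": "0009628",
    "response to temperature stimulus": "0009266",
    "response to cold": "0009409",
    "response to heat": "0009408",
    "response to radiation": "0009314",
    "cellular process": "0009987",
    "cellular response to stress": "0033554",
    "cellular response to DNA damage stimulus": "0006974",
    "DNA repair": "0006281",
    "response to hypoxia": "0001666",
    "defense response": "0006952",
    "response to wounding": "0009611",
    "wound healing": "0042060",
    "response to oxidative stress": "0006979",
    "behavior": "0007610",
    "jump response": "0007630",
    "system process": "0003008",
    "nervous system process": "0050877",
    "sensory perception": "0007600",
    "sensory perception of sound": "0007605",
    "sensory perception of smell": "0007608",
    "rhythmic process": "0048511",
    "circadian rhythm": "0007623",
    "rhythmic behavior": "0007622",
    "circadian behavior": "0048512",
    "locomotion": "0040011",
    "jumping": "0007629",
    "cell death": "0008219",
    "programmed cell death": "0012501",
    "apoptotic process": "0006915",
    "biological regulation": "0065007",
    "regulation of cellular process": "0050794",
    "regulation of programmed cell death": "0043067",
}

PATO = {
    "quality": "0000001",
    "abnormal": "0000460",
    "process quality": "0001236",
    "sensitivity of a process": "0001457",
    "decreased sensitivity of a process": "0001552",
    "morphology": "0000051",
    "size": "0000117",
    "increased size": "0000586",
    "has extra parts of type": "0002002",
}

CL = {"cell": "0000000", "neuron": "0000540"}

FBBT = {
    "anatomical entity": "10000000",
    "organism": "0000001",
    "multicellular structure": "0100313",
}

FBDV = {
    "life stage": "0000001",
    "embryonic stage": "0005289",
    "larval stage": "0005336",
    "pupal stage": "0005342",
    "mature adult stage": "0005369",
}

FBCV = {
    "phenotype": "0000001",
    "stress response defective": "0000408",
    "temperature response defective": "0000683",
    "cold stress response defective": "0000684",
    "heat stress response defective": "0000685",
    "radiation response defective": "0000687",
    "DNA repair defective": "0000423",
    "hypoxia response defective": "0000688",
    "defense response defective": "0000689",
    "wound healing defective": "0000690",
    "oxidative stress response defective": "0000691",
    "radiation resistant": "0000439",
    "behavior defective": "0000387",
    "circadian rhythm defective": "0000394",
    "circadian behavior defective": "0000679",
    "sensory perception defective": "0000692",
    "hearing defective": "0000693",
    "smell defective": "0000694",
    "jump response defective": "0000695",
    "jumping defective": "0000415",
    "increased cell size": "0000363",
    "increased cell number": "0000362",
    "cell death defective": "0000425",
    "apoptosis defective": "0000696",
}

_RESPONSE_TO_STRESS_DEF = (
    "Any process that results in a change in state or activity of a cell or "
    "an organism (in terms of movement, secretion, enzyme production, gene "
    "expression, etc.) as a result of a disturbance in organismal or "
    "cellular homeostasis, usually, but not necessarily, exogenous (e.g. "
    "temperature, humidity, ionizing radiation)."
)


def go_id(label: str) -> CurieId:
    return CurieId("GO", GO[label])


def pato_id(label: str) -> CurieId:
    return CurieId("PATO", PATO[label])


def cl_id(label: str) -> CurieId:
    return CurieId("CL", CL[label])


def fbbt_id(label: str) -> CurieId:
    return CurieId("FBbt", FBBT[label])


def fbdv_id(label: str) -> CurieId:
    return CurieId("FBdv", FBDV[label])


def fbcv_id(label: str) -> CurieId:
    return CurieId("FBcv", FBCV[label])


def _doc(prefix: str, ids: Mapping[str, str], parents: Mapping[str, Sequence[str]],
         namespace: Optional[str] = None) -> OntologyDocument:
    doc = OntologyDocument()
    for label in ids:
        term = OntologyTerm(
            id=CurieId(prefix, ids[label]),
            label=label,
            namespace=namespace,
            is_a=sorted(CurieId(prefix, ids[p]) for p in parents.get(label, ())),
        )
        doc.add(term)
    return doc


def make_mini_pato() -> OntologyDocument:
    return _doc("PATO", PATO, {
        "abnormal": ["quality"],
        "process quality": ["quality"],
        "sensitivity of a process": ["process quality"],
        "decreased sensitivity of a process": ["sensitivity of a process"],
        "morphology": ["quality"],
        "size": ["morphology"],
        "increased size": ["size"],
        "has extra parts of type": ["quality"],
    }, namespace="quality")


def make_mini_go() -> OntologyDocument:
    doc = _doc("GO", GO, {
        "response to stimulus": ["biological_process"],
        "response to stress": ["response to stimulus"],
        "response to abiotic stimulus": ["response to stimulus"],
        "response to temperature stimulus": ["response to abiotic stimulus"],
        "response to cold": ["response to stress", "response to temperature stimulus"],
        "response to heat": ["response to stress", "response to temperature stimulus"],
        "response to radiation": ["response to stress", "response to abiotic stimulus"],
        "cellular process": ["biological_process"],
        "cellular response to stress": ["response to stress", "cellular process"],
        "cellular response to DNA damage stimulus": ["cellular response to stress"],
        "DNA repair": ["cellular response to DNA damage stimulus"],
        "response to hypoxia": ["response to stress"],
        "defense response": ["response to stress"],
        "response to wounding": ["response to stress"],
        "wound healing": ["response to wounding"],
        "response to oxidative stress": ["response to stress"],
        "behavior": ["biological_process"],
        "jump response": ["behavior"],
        "system process": ["biological_process"],
        "nervous system process": ["system process"],
        "sensory perception": ["nervous system process"],
        "sensory perception of sound": ["sensory perception"],
        "sensory perception of smell": ["sensory perception"],
        "rhythmic process": ["biological_process"],
        "circadian rhythm": ["rhythmic process"],
        "rhythmic behavior": ["behavior", "rhythmic process"],
        "circadian behavior": ["rhythmic behavior", "circadian rhythm"],
        "locomotion": ["biological_process"],
        "jumping": ["locomotion"],
        "cell death": ["cellular process"],
        "programmed cell death": ["cell death"],
        "apoptotic process": ["programmed cell death"],
        "biological regulation": ["biological_process"],
        "regulation of cellular process": ["biological regulation"],
        "regulation of programmed cell death": ["regulation of cellular process"],
    }, namespace="biological_process")
    doc.get(go_id("response to stress")).textual_definition = _RESPONSE_TO_STRESS_DEF
    doc.get(go_id("response to stress")).definition_xrefs = ("GOC:mah",)
    return doc


def make_mini_cl() -> OntologyDocument:
    return _doc("CL", CL, {"neuron": ["cell"]}, namespace="cell")


def make_mini_fbbt() -> OntologyDocument:
    return _doc("FBbt", FBBT, {
        "organism": ["anatomical entity"],
        "multicellular structure": ["anatomical entity"],
    }, namespace="fly_anatomy")


def make_stage_ontology() -> OntologyDocument:
    doc = _doc("FBdv", FBDV, {
        "embryonic stage": ["life stage"],
        "larval stage": ["life stage"],
        "pupal stage": ["life stage"],
        "mature adult stage": ["life stage"],
    }, namespace="fly_development")
    order = ["embryonic stage", "larval stage", "pupal stage", "mature adult stage"]
    for earlier, later in zip(order, order[1:]):
        doc.get(fbdv_id(later)).relationships.append(
            ("immediately_preceded_by", fbdv_id(earlier))
        )
    doc.typedefs.append(Typedef(id="immediately_preceded_by", name="immediately preceded by"))
    return doc


def _eq(quality: str = "quality", entity: Optional[CurieId] = None,
        abnormal: bool = True, towards: Optional[CurieId] = None,
        equivalence: bool = True) -> EQDefinition:
    return EQDefinition(
        quality=pato_id(quality), entity=entity, towards=towards,
        abnormal=abnormal, equivalence=equivalence,
    )


def make_mini_dpo() -> OntologyDocument:
    """The mini phenotype ontology: every term asserted under the root (as
    legacy manual classification), patterns doing the rest."""
    doc = OntologyDocument()
    root = fbcv_id("phenotype")

    def add(label: str, definition: Optional[EQDefinition], *, is_a: Sequence[CurieId] = (),
            textual: Optional[str] = None) -> OntologyTerm:
        term = OntologyTerm(
            id=fbcv_id(label),
            label=label,
            namespace="fly_phenotype",
            is_a=sorted(set(is_a) | ({root} if label != "phenotype" else set())),
            definition_expression=definition,
            textual_definition=textual,
        )
        doc.add(term)
        return term

    add("phenotype", _eq(),
        textual="A quality of some anatomical structure, process or behavior "
                "that differs from wild-type.")
    # -- processual / stress-response fragment ------------------------------
    add("stress response defective", _eq(entity=go_id("response to stress")))
    add("temperature response defective", _eq(entity=go_id("response to temperature stimulus")))
    # the two legacy asserted subclasses, kept asserted alongside inference
    add("cold stress response defective", _eq(entity=go_id("response to cold")),
        is_a=[fbcv_id("stress response defective")])
    add("heat stress response defective", _eq(entity=go_id("response to heat")),
        is_a=[fbcv_id("stress response defective")])
    add("radiation response defective", _eq(entity=go_id("response to radiation")))
    add("DNA repair defective", _eq(entity=go_id("DNA repair")))
    add("hypoxia response defective", _eq(entity=go_id("response to hypoxia")))
    add("defense response defective", _eq(entity=go_id("defense response")))
    add("wound healing defective", _eq(entity=go_id("wound healing")))
    add("oxidative stress response defective", _eq(entity=go_id("response to oxidative stress")))
    # decreased sensitivity: no abnormality qualifier in the printed pattern,
    # so subsumption under the abnormal-qualified classes is (correctly) not
    # inferred and the classification stays asserted-only.
    add("radiation resistant",
        EQDefinition(quality=pato_id("decreased sensitivity of a process"),
                     entity=go_id("response to radiation")),
        textual="Animals are less sensitive than wild-type to radiation.")
    # -- behavioral fragment -------------------------------------------------
    add("behavior defective", _eq(entity=go_id("behavior")))
    add("circadian rhythm defective", _eq(entity=go_id("circadian rhythm")))
    add("circadian behavior defective", _eq(entity=go_id("circadian behavior")))
    add("sensory perception defective", _eq(entity=go_id("sensory perception")))
    add("hearing defective", _eq(entity=go_id("sensory perception of sound")))
    add("smell defective", _eq(entity=go_id("sensory perception of smell")))
    add("jump response defective", _eq(entity=go_id("jump response")))
    # necessary-only: classification stays neutral about behavior
    add("jumping defective", _eq(entity=go_id("jumping"), equivalence=False),
        textual="Flies fail to jump in a jump assay; no controls discount "
                "simple physical explanations.")
    # -- cell phenotypes -----------------------------------------------------
    add("increased cell size",
        EQDefinition(quality=pato_id("increased size"), entity=cl_id("cell")))
    add("increased cell number",
        EQDefinition(quality=pato_id("has extra parts of type"),
                     towards=cl_id("cell"),
                     entity=fbbt_id("multicellular structure")))
    add("apoptosis defective", _eq(entity=go_id("apoptotic process")))
    # -- union: cell death defective ----------------------------------------
    op_a = OntologyTerm(
        id=CurieId("AP", "00004251"),
        label="cell death defective (operand: programmed cell death)",
        subsets=[ANONYMOUS_PATTERN_SUBSET],
        definition_expression=_eq(entity=go_id("programmed cell death")),
    )
    op_b = OntologyTerm(
        id=CurieId("AP", "00004252"),
        label="cell death defective (operand: regulation of programmed cell death)",
        subsets=[ANONYMOUS_PATTERN_SUBSET],
        definition_expression=_eq(entity=go_id("regulation of programmed cell death")),
    )
    doc.add(op_a)
    doc.add(op_b)
    union = OntologyTerm(
        id=fbcv_id("cell death defective"),
        label="cell death defective",
        namespace="fly_phenotype",
        is_a=[root],
        union_operands=(op_a.id, op_b.id),
        definition_expression=EQDefinition(
            operands=(op_a.definition_expression, op_b.definition_expression)
        ),
    )
    doc.add(union)
    return doc


def make_named_fixtures() -> Dict[str, OntologyDocument]:
    return {
        "mini-pato": make_mini_pato(),
        "mini-go": make_mini_go(),
        "mini-cl": make_mini_cl(),
        "mini-fbbt": make_mini_fbbt(),
        "stage-ontology": make_stage_ontology(),
        "mini-dpo": make_mini_dpo(),
    }


def default_imports() -> Dict[str, TermGraph]:
    """Prefix-bound import graphs for classifying the mini phenotype
    ontology."""
    return {
        "PATO": make_mini_pato().term_graph(),
        "GO": make_mini_go().term_graph(),
        "CL": make_mini_cl().term_graph(),
        "FBbt": make_mini_fbbt().term_graph(),
    }


def default_stage_chain() -> StageChain:
    return StageChain.from_obo_document(make_stage_ontology())


def write_fixture_files(out_dir) -> List[str]:
    """Write every named fixture as an OBO file; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, doc in sorted(make_named_fixtures().items()):
        path = out_dir / f"{name}.obo"
        path.write_text(write_obo(doc))
        written.append(str(path))
    return written


# --------------------------------------------------------------------------
# Seeded random instances
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random instance; generation is a pure function of
    this spec."""

    seed: int
    n_terms: int = 8
    n_entities: int = 16
    n_qualities: int = 5
    max_parents: int = 2
    union_rate: float = 0.15
    necessary_rate: float = 0.15
    prefix: str = "PX"

    def __post_init__(self) -> None:
        if self.n_terms < 1 or self.n_entities < 2 or self.max_parents < 1:
            raise ValueError("fixture spec outside documented limits")


def random_dag(rng: random.Random, prefix: str, n: int, max_parents: int) -> TermGraph:
    """A random rooted DAG: node i links to 1..max_parents earlier nodes."""
    nodes = [CurieId(prefix, f"{i:07d}") for i in range(n)]
    edges = []
    for i in range(1, n):
        k = rng.randint(1, min(max_parents, i))
        parents = rng.sample(range(i), k)
        for p in parents:
            edges.append((nodes[i], nodes[p]))
    return TermGraph.from_edges(edges, nodes=nodes)


def random_instance(spec: FixtureSpec) -> Tuple[OntologyDocument, Dict[str, TermGraph]]:
    """A random phenotype document plus import graphs.

    Entities come from a random DAG under prefix ``EX``; qualities from a
    random DAG rooted at bare 'quality' under prefix ``QX``.  Definitions
    are equivalent-class by default, necessary-only or unions at the
    configured rates.  Identical specs yield byte-identical documents.
    """
    rng = random.Random(spec.seed)
    entities = random_dag(rng, "EX", spec.n_entities, spec.max_parents)
    qualities = random_dag(rng, "QX", spec.n_qualities, 1)
    entity_ids = sorted(entities.nodes)
    quality_ids = sorted(qualities.nodes)

    def pattern(equivalence: bool = True) -> EQDefinition:
        return EQDefinition(
            quality=rng.choice(quality_ids),
            entity=rng.choice(entity_ids),
            towards=rng.choice(entity_ids) if rng.random() < 0.2 else None,
            abnormal=rng.random() < 0.7,
            equivalence=equivalence,
        )

    doc = OntologyDocument()
    for i in range(spec.n_terms):
        tid = CurieId(spec.prefix, f"{i:07d}")
        roll = rng.random()
        if roll < spec.union_rate:
            ops = []
            for j in range(2):
                op = OntologyTerm(
                    id=CurieId("AX", f"{i:05d}{j:02d}"),
                    label=f"pattern operand {i}.{j}",
                    subsets=[ANONYMOUS_PATTERN_SUBSET],
                    definition_expression=pattern(),
                )
                doc.add(op)
                ops.append(op)
            doc.add(OntologyTerm(
                id=tid, label=f"random phenotype {i}",
                union_operands=tuple(o.id for o in ops),
                definition_expression=EQDefinition(
                    operands=tuple(o.definition_expression for o in ops)
                ),
            ))
        else:
            equivalence = roll >= spec.union_rate + spec.necessary_rate
            doc.add(OntologyTerm(
                id=tid, label=f"random phenotype {i}",
                definition_expression=pattern(equivalence=equivalence),
            ))
    return doc, {"EX": entities, "QX": qualities}
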