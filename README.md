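# flypheno

A toolkit for building and releasing pattern-formalised phenotype
ontologies, of the kind used to curate *Drosophila* phenotypes: it reads and
writes OBO 1.4, models entity–quality (EQ) class definitions, classifies
them structurally against imported entity ontologies, derives textual
definitions automatically, and implements a lethal-phase system for
recording and reasoning about the timing and rate of death in mutant
populations.

## Who it is for

Ontology engineers and curators who maintain a phenotype vocabulary as a set
of *patterns* over external ontologies (a quality ontology such as PATO, a
process ontology such as the GO, cell and anatomy ontologies) and want the
classification to be computed, not hand-maintained — plus the release
machinery to publish both the pattern-bearing source and a pre-reasoned
"simple" artifact.

## The model

A phenotype class is an EQ expression

```
Q  ⊓  ∃inheres_in.E  ⊓  ∃qualifier.abnormal  [⊓  ∃towards.T]
```

with `Q` a quality, `E` the bearer entity (process, cell, structure), the
`abnormal` qualifier marking deviation from wild-type, and `towards` used by
relational qualities ('has extra parts of type' towards cell).  The
phenotype root is `quality ⊓ ∃qualifier.abnormal`.  Unions
(`A ∪ B`) and necessary-condition-only definitions are supported.
Subsumption is structural: `d1 ⊑ d2` iff every conjunct of `d2` is entailed
by `d1` under the reflexive-transitive is_a closure of the imports, with
`d1 ⊑ A ∪ B` iff `d1 ⊑ A` or `d1 ⊑ B`, and `A ∪ B ⊑ d2` iff both operands
are.

Lethal-phase terms pair a **mortality band** — a closed integer interval of
increased-mortality percent, with cutoffs *some* ≥ 5, *most* ≥ 50,
*all* ≥ 98 — with an **age window** over a chain of life stages linked by
`immediately_preceded_by` (Allen's *meets*).  Age windows (`during S`,
`precedes S`, `before end of S`, `any`) denote sets of death-stage indices,
so `t1 ⊑ t2` iff band ⊆ band and window ⊆ window.  A finite-population model
checker provides an independent semantic oracle for this rule, and the
seven-relation Allen subset (p, P, m, M, d, s, f, plus equality) with its
composition table supports validating stage arithmetic.

## Worked example

```
$ python examples/autoclassify_phenotypes.py
subclasses of 'stress response defective':
  FBcv:0000423  DNA repair defective
  FBcv:0000684  cold stress response defective
  FBcv:0000685  heat stress response defective
  FBcv:0000687  radiation response defective
  FBcv:0000688  hypoxia response defective
  FBcv:0000689  defense response defective
  FBcv:0000690  wound healing defective
  FBcv:0000691  oxidative stress response defective

superclasses of 'cold stress response defective':
  FBcv:0000001  phenotype
  FBcv:0000408  stress response defective
  FBcv:0000683  temperature response defective

26 direct classifications, 14 inferred (54%).
```

'stress response defective' has only two asserted subclasses in the bundled
fixture; the other six placements — including 'DNA repair defective' — are
inferred from the process ontology's structure, and 'cold stress response
defective' lands under both the stress and the temperature groupings
without either link being asserted.  The final line is the
asserted-vs-inferred accounting over the transitively reduced hierarchy.

Other examples: `lethal_phase_reasoning.py` (generate, classify and
annotate lethal-phase terms), `textual_definitions.py` (automated
definitions), `release_pipeline.py` (the full release flow).

## Command line

```
flypheno release --ontology dpo.obo --import GO=go.obo --import PATO=pato.obo \
    --out release/ --generate-lethal
```

emits `<name>-full.obo`, the pre-reasoned `<name>-simple.obo`, `stats.tsv`,
`edges.tsv` (per-edge provenance), `findings.tsv`, and optionally the
generated lethal-phase set.  Further subcommands: `validate`, `module`
(paths-to-root extraction), `classify`, `textdefs`, `lethal-generate`,
`fixtures`.

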