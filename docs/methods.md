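# Methods

## Scope and model

flypheno implements the formalisation machinery of a pattern-based
phenotype ontology: entity–quality (EQ) class definitions over imported
entity ontologies, structural classification, automated textual
definitions, a lethal-phase system (mortality bands over age-constrained
populations), paths-to-root module extraction, and a deterministic release
pipeline producing both a pattern-bearing and a pre-reasoned artifact.

The description-logic fragment handled by the structural classifier is
existential-conjunctive (EL-style) plus top-level unions: a definition is a
quality genus with optional `inheres_in`, `towards` and `abnormal`
conjuncts, or a union of such patterns.  This covers the EQ axioms the
toolkit targets; it deliberately excludes negation, disjointness, role
chains and general OWL 2 reasoning.  The lethality fragment — which in OWL
terms needs data ranges and universal quantification over population
members — is handled by a dedicated interval semantics (below) rather than
by the EQ classifier, since the two pattern families never mix within one
definition.

Only is_a edges participate in classification.  Other relationships are
preserved through I/O but ignored by the reasoner: propagating phenotype
subsumption along part_of or regulates would be unsound for these patterns.

## Structural subsumption and classification

`d1 ⊑ d2` iff every conjunct of `d2` is matched by the corresponding
conjunct of `d1` under the reflexive-transitive is_a closure of the
imports; unions distribute in the usual way (`d1 ⊑ A∪B` iff either; `A∪B ⊑
d2` iff both).  Fillers are compared within the import graph of their
prefix; an unresolved filler is an error, never a silent "false".

Document classification takes every ordered pair of defined terms, keeps
subsumptions whose *parent* side is an equivalent-class definition
(necessary-condition-only definitions place their term under matching
classes but attract no descendants), merges asserted is_a links, condenses
strongly connected components (mutual subsumption) into equivalence groups
reported as curator findings, and transitively reduces.  Each surviving
direct edge carries provenance: `asserted` if present among the asserted
links, else `inferred`.  All iteration is in id-sorted order, making every
output byte-reproducible.

The asserted-vs-inferred statistics count direct (reduced) edges;
`percent_inferred` uses half-up integer rounding.

## Temporal model

Life stages form a single linear chain, consecutive stages related by
`immediately_preceded_by` (the inverse of Allen's *meets*).  Death is
modelled at stage granularity: one death-stage index per organism, no
within-stage timing — the patterns discriminate only at stage level.

The seven-relation Allen subset (p, P, m, M, d, s, f) plus equality is
implemented with the *standard* composition table, restricted so that any
composed base relation outside the subset is reported with an `other`
marker.  The table is verified in the test suite against brute-force
enumeration of integer-endpoint interval triples.  (A note on transitivity:
of the subset, precedes, preceded_by and during are transitive; meets and
met_by are not — `m;m = p`.  Accounts that list meets among the transitive
relations are treating "stage n+2 is two steps later" loosely;
the composition table is the ground truth here.)

Age constraints denote index sets: `precedes(S_k) = {0..k-1}`,
`during(S_k) = {k}`, `before_end_of(S_k) = {0..k}`, `any` = all indices.
`before_end_of` is *defined* as during ∪ precedes; this reading is what
makes the lethal-phase nesting (during S ⊑ before end of S ⊑ before end of
S+1 …) come out.  Constraint subsumption is index-set inclusion.

## Lethal-phase system

Default cutoffs: some ≥ 5% (the hard non-zero floor for 'increased
mortality', a rule of thumb rather than a strict biological threshold),
most ≥ 50%, all ≥ 98% ('lethal' tolerates rare escapers).  Rates are whole
numbers in [0, 100], recorded as increase over the wild-type rate for the
same stage; strict printed bounds normalise losslessly over the integers
(">50" ≡ "≥51").

Two boundary conventions are preserved as printed: the *most* band is
[50, 100] while 'partially lethal - majority die' is [51, 98] (from
">50, <= 98"), so the two are deliberately not the same interval.  'lethal'
is [98, 100]: a reading of the band as "≤ 98" would make 'lethal' overlap
'partially lethal' almost entirely and break the nested classification, so
the upper-bounded variant is treated as an erratum of its source
material.  The per-stage "die during S" / "die before end of S" terms have
no canonical printed axioms; their (band, age-window) encoding here is this
toolkit's formalisation, chosen so that the flat set classifies into the
expected nesting.  'short lived' (increased mortality during the adult
stage) is generated only behind a flag, as this toolkit's reading of a
term that is described but not axiomatised.

Subsumption is band containment ∧ window containment.  Consequences worth
knowing: for the first stage, "during" and "before end of" coincide, and
'lethal' coincides with "all die before end of" the last pre-adult stage —
these show up as reported equivalence groups, which is semantically correct
rather than a defect.  Generated ids are minted in a reserved `LP`
namespace from a SHA-1 of (quantifier, mode, stage), so regeneration is
stable; the four stage-spanning core terms keep their conventional FBcv
ids.

### Model-checking oracle

The independent oracle enumerates finite populations: up to 4 cohorts,
each a (weight, fate) pair with weight drawn from the coarse grid
{5, 50, 51, 97, 98, 100} (the band boundaries and their neighbours) and
fate either death during a specific stage or survival, total weight capped
at 100.  A population satisfies a term iff the total weight dying inside
the term's age window lies in its band; `t1 ⊑ t2` iff no enumerated
population satisfies t1 but not t2.  On every ordered pair of *generated*
terms this agrees exactly with the interval rule (verified for chains of
length 2–5).  The agreement is not an accident but also not universal: for
arbitrary term pairs whose parent band has an upper bound below 100, mass
falling outside the child's window can push the parent's window total out
of band; among the generated set the only upper-bounded band
(partially-lethal's) is contained in no other generated band, so the case
never arises.

### Annotation

A mortality observation (per-stage whole-number percentages, wild-type
baseline already subtracted) supports a term iff the observed mass in the
term's window lies in its band.  The annotator returns the antichain of
most specific applicable terms, collapsing equivalence classes onto the
representative with the tightest age-window wording (during, then before
end of, then precedes, then any).

## OBO dialect

Target dialect is OBO 1.4; OBO↔OWL translation is out of scope.  EQ
equivalent-class definitions use standard `intersection_of` lines (exactly
one genus).  Two encodings are this toolkit's own conventions, since no
standard tag fits:

* unions: `equivalent_union_of: <id> <id> ...`, each operand an auxiliary
  stanza tagged `subset: anonymous_pattern` carrying its own
  intersection_of lines;
* necessary-condition-only patterns: `necessary_pattern:` lines with the
  same grammar as intersection_of.

Both are registered via `subsetdef` header lines so third-party parsers
skip them safely (verified against an independent OBO reader in the test
suite).  Unknown tags round-trip as opaque lines.  Dangling references are
findings by default and errors under `--strict`: imported-module workflows
legitimately carry references resolved elsewhere.  The writer is fully
deterministic (terms sorted by id, fixed tag order), and parse∘write is a
fixed point after one normalisation.

Module extraction follows the paths-to-root strategy: a used term plus
everything on its is_a paths to any root, with all edges among retained
nodes; non-is_a relationships are kept when both endpoints are retained.
Locality-based module extraction is a non-goal.

## Automated textual definitions

Terms defined exactly as `quality ⊓ ∃inheres_in.<GO process> ⊓
∃qualifier.abnormal`, with the *bare* quality genus and no manual
definition, receive generated text quoting the GO term's label, short-form
id and definition.  More specific genera are excluded — reliable prose
cannot be derived for them — and manual definitions always win.  Rolling
is idempotent and re-run on every release, so deleting a manual definition
re-enables generation.  Plain ASCII apostrophes are used throughout.

## Fixtures and problem sizes

The bundled miniature ontologies are the toolkit's test bed and demo data:
a 9-term quality ontology, a 36-term process ontology carrying the
stress-response and behavior fragments, small cell/anatomy ontologies, a
4-stage life-stage chain and a 24-term phenotype ontology exercising every
pattern variant (plain, specific-genus, towards, union, necessary-only).
The process fragment is constructed so that 'stress response defective'
gains 8 subclasses by inference and 'response to cold' sits under both
stress and temperature groupings.  What passing tests on these fixtures do
*not* show: behaviour at real-ontology scale (tens of thousands of terms),
interaction with relations beyond is_a, or the fidelity of any specific
real ontology's content — the fixtures are structural miniatures, not
excerpts of a release.

Seeded random instances (pure functions of a `FixtureSpec`) drive the
property tests: random rooted DAG imports and random EQ definitions, with
union and necessary-only variants at configurable rates.  Oracle-equivalence
tests run at deliberately small scale — definitions over ≤30-node imports,
documents of ≤12 phenotype terms, 500+ random subsumption pairs, stage
chains of length 2–5 — where exhaustive brute force is feasible; the
algorithms themselves are size-independent.

## Numerical and tie-breaking choices

* All iteration id-sorted; outputs byte-identical across runs.
* Transitive reduction output sorted by (child, parent).
* Equivalence groups condense onto the id-least member.
* Percent statistics: half-up integer rounding.
* Empty module request returns the empty graph; a single-term document
  classifies to zero edges; a hierarchy of zero direct edges reports an
  inferred fraction of 0.

## Known limitations

* No general OWL reasoning: consistency checking beyond the pattern
  fragment (e.g. with a DL reasoner) is out of scope.
* One linear stage chain; overlapping stage subdivisions (instars within
  the larval stage) are not represented.
* The comparative (vs wild-type) nature of phenotypes is not formalised
  beyond the `abnormal` qualifier.
* Multi-feature phenotypes and assay-defined classes have no pattern here,
  matching their undefined status in the vocabularies this targets.
* Mortality observations are single tables of whole-number percentages; no
  uncertainty, censoring or replicate handling.
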