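# Methods

This note documents the model implemented by `dxlattice`, the choices made
where the design was genuinely open, what the synthetic generators emulate,
and the known limitations.

## The derivative model

### Anatomy order

The anatomical order `s ≤A t` is plain directed reachability over the
union of `is_a` and the two part-whole roles
(`anatomic_structure_is_physical_part_of`,
`anatomic_structure_has_location`), taken reflexively.  Both part roles
are treated as transitive and freely composable with `is_a`.  This is a
deliberate modelling commitment, not an oversight: it reproduces the
source ontology's own propagation behavior, including its questionable
consequences — a Birbeck granule is "in" skin through the chain granule →
Langerhans cell → epidermis → skin, so a skin reflexive part covers
cell-level organelles.  The transitivity of part-of across granularity
levels is philosophically contested; the package reproduces the source
semantics rather than repairing them, and the audit stage is where the
consequences become visible.  Cycles in the combined anatomy graph are
fatal by default (`CycleError`); `collapse_cycles` opt-in merges each
strongly connected component into its lexicographically smallest member.

### Reflexive parts (S-nodes)

A primary site is read as "the site or any of its parts".  Each collected
topography `X` yields one class `RP(X) ≡ X ⊔ ∃part_of.X`, with
`RP(s) ⊑ RP(t)` iff `s ≤A t`.  Internally RP classes are primitive nodes
carrying the defined order; the union definition is emitted only at
serialization.  Topography collection applies **ancestor completion** by
default: asserted site fillers plus everything above them under `≤A`.
Completion is required for coarse shared ancestors (a "large intestine
reflexive part" that no concept asserts directly) to exist as classes;
whether a deployment wants asserted-only granularity is exposed as
`ancestor_completion: on|off` because the right choice depends on the
source ontology's annotation habits and is not derivable from first
principles.

### Morphology axis

One class per distinct annotated ICD-O-3 code, under six behavior
classes fixed by the code's fifth digit:

| digit | behavior class |
|-------|----------------|
| 0 | BENIGN |
| 1 | UNKNOWN_BENIGN_MALIGNANT |
| 2 | IN_SITU |
| 3 | MALIGNANT_PRIMARY |
| 6 | MALIGNANT_METASTATIC |
| 9 | UNKNOWN_PRIMARY_METASTATIC |

The axis is **flat** below the behavior level: no histological hierarchy
is asserted between specific codes, so `9121/0` (cavernous hemangioma)
and `9120/0` (hemangioma NOS) are incomparable even though their labels
suggest specialization.  This is corroborated by the colon cavernous
hemangioma example, whose direct diagnosis classes include both codes
side by side; building a histology hierarchy would require information
the annotations do not carry.  Codes are compared as full `HHHH/B`
strings — the same histology with two behavior digits is two classes,
consistent with ICD-O-3's rule that a morphology has exactly one
behavior.  The digit table is configurable only through an explicit
override map.

### Refined concepts and retention

Each neoplasm concept inherits the morphology annotations and site
fillers of all its `is_a` ancestors (including itself).  Inheritance is
deliberately not filtered for consistency: an in-situ concept that
inherits an invasive morphology through a dubious `is_a` link keeps both,
because surfacing exactly that contradiction is the audit's purpose.

Candidates `D(m, t)` are streamed from the cross product of the
morphology axis (behavior classes included — retained classes may be as
coarse as "malignant, primary site: cecum reflexive part") and the RP
lattice, in O(1) memory per pair.  A candidate is retained iff some
concept satisfies it:

    ∃ mc ∈ inherited_morphs(C): mc ⊑ m   and   ∃ s ∈ inherited_sites(C): s ≤A t

The retention scan is indexed (per concept, the up-sets of its inherited
morphologies and sites are expanded once and their product accumulated),
which makes the full product feasible at scale; enumeration order cannot
affect the result, since retention is a pure membership property of each
candidate.  The naive concept × candidate double loop is kept in
`dxlattice.oracle` as the test oracle.

Note that satisfaction by a bare concept requires an inherited morphology:
a concept carrying only sites (e.g. a "malignant X neoplasm" with no
ICD-O-3 annotation) satisfies nothing by itself.  Behavior information
joins only at ICD-10 binding time, where the code's block supplies the
behavior restriction — this is what makes `C18.0` an instance of
behavior-level classes even though its mapped concept has no annotation.

### Subsumption engine

The diagnosis order is the product order.  All three orders are computed
structurally: precomputed reachability closures, a two-level morphology
order, and their product.  In this EL-style fragment (conjunctions and
existentials over two roles, no negation, no role hierarchies) the
structural computation coincides with DL subsumption, so a reasoner is
unnecessary; the independent saturation oracle in the test suite is the
guard against implementation drift.  All set-valued outputs are sorted
lexicographically; generated IRIs are deterministic
(`<ns>RP_<anatomyId>`, `<ns>DX_<morphCode>_<anatomyId>`).

## Terminology binding

ICD-10 block → behavior defaults: C00–C76 malignant primary, C77–C79
excluded (secondary), **C80–C97 malignant primary**, D00–D09 in situ,
D10–D36 benign, D37–D48 excluded (uncertain).  Two notes: (i) secondary
malignancies are conventionally C77–C79; descriptions that instead name
"C81–C96" as the secondary block confuse it with the lymphoid/
haematopoietic codes — C81–C96 are primary tumors and must stay in scope
for any hematopoietic evaluation stratum to exist; (ii) the ranges ship
as configuration, so a deployment tracking a different revision can
override them.

When a code maps to several source concepts through CUIs, the satisfied
sets are unioned before minimization (one-to-many binding is normal in
metathesaurus data).  Binding is total: every code receives exactly one
status (`BOUND`, `UNMAPPED`, `NON_ANATOMY_ONLY`, `EXCLUDED_SCOPE`,
`NO_SITE`), and status counts are conserved per system.  For
topography-morphology combinations, the mapped anatomy concept itself
(not its reflexive part) enters satisfaction, mirroring instance
semantics.

## Audit

A code is multi-instantiated when its direct-class antichain has more
than one element.  Two detectors interpret the signal: behavior
conflicts (direct classes spanning ≥2 behavior classes — biologically
impossible for a single tumor state, hence a wrong mapping or a wrong
`is_a` link upstream) and incomparable sites (direct classes on mutually
`≤A`-incomparable bases — candidate missing part-of links or `is_a`
overloading).  No threshold separates overloading from legitimately
multifocal descriptions; all cases are reported uniformly for human
review.

## Evaluation

A gold mapping is evaluable when its three codes all bind.  *Related*
means the ICD-10 code and the combination satisfy at least one common
diagnosis class; the minimal common classes are the shared "branches"
(the only order-theoretic reading consistent with reporting direct
types), and >1 minimal class counts as multi-branch.  *Rebuilt* means
the gold ICD-10 code is among the predicted codes of its combination
under nearest-neighbour mapping: distance between a code and a
combination is the minimum, over (direct class of code) × (minimal
satisfied class of combination), of the common-ancestor edge distance on
the diagnosis Hasse diagram (up-steps only, `∞` without a common
ancestor).  Ties are preserved — all argmin codes are predicted and the
combination is marked non-unique — because collapsing ties would
silently hide exactly the ambiguity worth reporting.  The distance is
symmetric with d(x,x)=0 but is not a metric (no triangle inequality is
asserted), and it traverses the diagnosis lattice only; distances
through raw RP or morphology edges would weight site- and
histology-steps identically and were not pursued.  The hematopoietic
stratum defaults to ICD-10 C81–C96 or morphology histology 9590–9993,
configurable.

## Synthetic data

`build_example_fixture` is the deterministic worked-example bundle: breast
and LOQ, the GI partonomy with the cecum/colon/colorectal gap, C9329
with five asserted sites, the hemangioma pair, the in-situ/invasive
carcinoma pair above a stage-0 breast cancer, a topography mapped only
to a non-anatomical concept, the Birbeck-granule chain, and
adenocarcinoma concepts that make behavior-level diagnosis classes
retainable.  Its truth tables are replayed against the independent
saturation oracle at construction time, so an inconsistent bundle cannot
be built.  What it does **not** emulate: real NCIm crosswalk noise at
scale, lexical variation, the tens of thousands of concepts of a real
terminology, or annotation sparsity — passing on the bundle shows the
algorithms implement the intended semantics exactly, not that a given
real ontology is clean.

`random_ontology` draws layered DAGs (every edge points to a strictly
earlier node, hence acyclic by construction) with per-pair edge
probabilities, random site fillers and annotations; it drives the
engine/oracle equivalence tests (20 seeds × ≤40 concepts by default).
`scale_ontology` builds a sparse 5,000-anatomy / 400-neoplasm /
994-morphology model — chosen as the largest size that keeps the full
streamed product (5 million candidates) and a 10,000-candidate sampled
brute-force cross-check comfortable on one CPU — for the scale smoke
run.  `plant_gold_standard` keeps only combinations with a strictly
unique nearest code, so recovery is guaranteed by construction and any
failure is an implementation defect, not sampling noise.

## Numerical and procedural choices

- Determinism: no wall-clock content in artifacts; a config hash
  (excluding output location) and the seed stamp every table; identical
  config + seed ⇒ byte-identical outputs.
- Hasse diagrams via transitive reduction; antisymmetry is checked and a
  violating pair is reported before reduction.
- Degenerate inputs: empty ontologies yield empty lattices and all-zero
  reports; an empty morphology axis still contains its seven structural
  nodes; evaluation of an empty gold table is all zeros rather than an
  error.
- The oracle refuses models above 5,000 candidate pairs; it exists for
  equivalence testing, not production use.

## Limitations

- Coverage is bounded by the crosswalk: codes without CUI links stay
  `UNMAPPED`; no lexical fallback mapping is attempted.
- Metastatic (`/6`) and uncertain (`/1`, `/9`) behaviors are excluded
  from scope rather than modelled.
- The flat morphology axis cannot express histological specialization;
  related codes are incomparable unless a behavior class relates them.
- Granularity of reflexive parts follows the source partonomy all the
  way down to organelles; no granularity filtering is applied.
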