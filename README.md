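# dxlattice

**Automatic construction of a derivative diagnosis lattice that integrates
ICD-10 and ICD-O-3 through an NCIt-like oncology ontology.**

Cancer diagnoses reach electronic health records through structurally
incompatible classifications: ICD-10 encodes a neoplasm diagnosis as a
single code combining behavior and site (`C50.2` *Malignant neoplasm,
upper-inner quadrant of breast*), while ICD-O-3 splits it into a
topography code (site of origin) and a morphology code (histology plus a
behavior digit).  No code in one system is equivalent to a code in the
other; the only correspondences that exist are between a diagnosis and a
topography–morphology *combination*.  `dxlattice` is a tool for cancer
registries, terminology services and ontology auditors that builds the
bridging model automatically from a reference ontology, and then uses the
same model to audit that ontology for inconsistencies.

## The model

From a source ontology providing `is_a` edges, two part-whole relations
over anatomy, primary-site assertions and ICD-O-3 morphology annotations,
the tool generates three class hierarchies:

1. **Reflexive-part topographies** (S-nodes).  For each anatomical entity
   *X* involved in a diagnosis definition, a class
   `RP(X) ≡ X ⊔ ∃part_of.X` — the site together with all its parts —
   ordered by reachability over `is_a` and both part roles:
   `RP(s) ⊑ RP(t)` iff `s ≤A t`.
2. **Behavior-stratified morphologies.**  One class per annotated
   ICD-O-3 code `HHHH/B`, placed under one of six behavior classes
   (benign `/0`, uncertain `/1`, in situ `/2`, malignant primary `/3`,
   metastatic `/6`, uncertain primary/metastatic `/9`).
3. **Diagnoses.**  Candidate classes
   `D(m, t) ≡ ∃has_finding.m ⊓ ∃has_primary_site.RP(t)` are streamed from
   the full morphology × topography product; a candidate is retained only
   when at least one source concept satisfies it, i.e. inherits (through
   its `is_a` ancestors) a morphology below `m` and a site inside `t`.
   The retained classes form a lattice under the product order
   `D(m,t) ⊑ D(m',t')  ⇔  m ⊑ m'  ∧  t ≤A t'`.

Subsumption in this restricted pattern is computed structurally with
graph algorithms (sound and complete here — no DL reasoner required), and
an independent rule-saturation oracle re-derives every relation in the
test suite.

Terminology codes then instantiate the model through a CUI crosswalk
(NCI-Metathesaurus style): ICD-O-3 morphologies bind by code, ICD-O-3
topographies bind to the minimal reflexive parts above their mapped
anatomy concepts, and ICD-10 codes bind to the minimal diagnosis classes
satisfied by their mapped concepts *plus* the behavior restriction implied
by their ICD-10 block.  Codes instantiating several incomparable classes
are flagged: incomparable sites point at missing part-of links or `is_a`
overloading in the source, and mixed behaviors (an in-situ code inheriting
an invasive morphology) expose inconsistent subsumptions.  Finally, the
model is compared against a SEER-style conversion table: shared diagnosis
branches per gold mapping, and mapping reconstruction by minimum
edge-based distance on the diagnosis Hasse diagram.

## Worked example

The built-in bundle (`dxlattice.fixtures.build_example_fixture`) encodes the
classic worked examples: the breast-quadrant partonomy, the
cecum/colon/colorectal gap, the colon cavernous hemangioma, the in-situ
breast cancer conflict, and the Birbeck-granule partonomy chain.

```python
from dxlattice.fixtures import build_example_fixture
from dxlattice.pipeline import build_model, bind_terminologies
from dxlattice.terminology import System, TerminologyCode, derive_icd10_behavior

bundle = build_example_fixture()
model = build_model(bundle.onto)
icd10 = [TerminologyCode(c, System.ICD10, l, derive_icd10_behavior(c))
         for c, l in bundle.icd10]
bindings = bind_terminologies(model, bundle.crosswalk_table(), icd10,
                              [c for c, _ in bundle.icdo3_topo],
                              [c for c, _ in bundle.icdo3_morph])
print(f"{len(model.rp)} reflexive parts, "
      f"{len(model.axis.candidate_morph_ids())} morphology classes, "
      f"{model.n_candidates} candidates, {len(model.dx)} retained diagnoses")
for code in ("C18.0", "D05"):
    b = bindings.icd10[code]
    print(code, "->", ", ".join(f"D({m}, {t.split(':')[1]})"
                                for m, t in b.direct_classes))
```

prints

```
11 reflexive parts, 13 morphology classes, 143 candidates, 46 retained diagnoses
C18.0 -> D(MALIGNANT_PRIMARY, CECUM), D(MALIGNANT_PRIMARY, COLON), D(MALIGNANT_PRIMARY, COLORECTAL_REGION)
D05 -> D(8010/2, C12971), D(8010/3, C12971)
```

`C18.0` (malignant neoplasm of cecum) lands on **three** mutually
incomparable diagnosis classes because its mapped concept asserts five
primary sites and the source ontology relates none of cecum, colon and
colorectal region to each other — exactly the multi-instantiation signal
the audit stage reports as candidate missing part-of links.  `D05`
(carcinoma in situ of breast) lands on one in-situ (`8010/2`) and one
invasive (`8010/3`) class and is flagged as a behavior conflict: a tumor
cannot be both at once, so one inherited mapping in the source is wrong.

The same pipeline is available from the shell:

```
dxlattice simulate --out fixture
dxlattice run --ontology-path fixture/ontology \
    --icd10-path fixture/icd10.csv \
    --icdo3-topo-path fixture/icdo3_topography.csv \
    --icdo3-morph-path fixture/icdo3_morphology.csv \
    --crosswalk-path fixture/crosswalk.tsv \
    --seer-path fixture/seer_gold.tsv --output-dir out
```

which writes the model as SKOS/OWL Turtle (`derivative_model.ttl`),
binding, audit and evaluation tables (TSV + JSON) and a run summary.
Given the same configuration and seed, artifacts are byte-identical
across runs.  Real inputs (an OWL/Turtle ontology subset, MRCONSO-style
RRF crosswalks, SEER conversion TSVs) are supported through the same
flags; see `docs/methods.md` for formats and semantics.

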