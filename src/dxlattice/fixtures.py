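"""Synthetic fixture bundles: the worked-example ontology fragment,
randomized ontologies, and planted gold standards.

``build_example_fixture`` produces a small, fully deterministic source
ontology exercising every interesting configuration the method has to
handle: a breast partonomy with a lower-outer quadrant, a gastrointestinal
partonomy in which cecum, colon and colorectal region are all parts of the
large intestine but mutually unrelated, a malignant cecum neoplasm concept
(C9329) asserting five primary sites at once, a benign hemangioma pair
whose specific and NOS morphologies are incomparable, an in-situ breast
cancer concept (C3641) inheriting both an in-situ and an invasive
morphology through its is_a ancestry, an ICD-O-3 topography mapped only to
a non-anatomical concept, and a cell-level partonomy chain (Birbeck
granule inside Langerhans cell inside epidermis inside skin) that the
part-whole propagation happily traverses.  The bundle carries truth tables
for the expected bindings and direct classes; when ``verify=True`` (the
default) they are replayed against the independent saturation oracle at
build time, so a bundle that does not match its own truth cannot be
constructed.

``random_ontology`` generates seeded random layered DAGs (acyclic by
construction: every edge points from a higher topological rank to a lower
one) for property and equivalence testing.  ``plant_gold_standard``
samples topography-morphology combinations and keeps those with a unique
nearest ICD-10 code, guaranteeing recoverability by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .core import Axis, Concept, RoleKind, SourceOntology
from .oracle import brute_force_oracle
from .terminology import CuiMapRecord, CuiCrosswalk

__all__ = [
    "FixtureBundle",
    "GenParams",
    "build_example_fixture",
    "random_ontology",
    "plant_gold_standard",
    "write_fixture_files",
]

NS = "NCIT:"

# -- anatomy ids --------------------------------------------------------
ANATOMIC_ROOT = NS + "ANATOMIC_STRUCTURE"
GI_SYSTEM = NS + "GI_SYSTEM"
INTESTINE = NS + "INTESTINE"
LARGE_INTESTINE = NS + "LARGE_INTESTINE"
CECUM = NS + "CECUM"
COLON = NS + "COLON"
COLORECTAL = NS + "COLORECTAL_REGION"
RECTOSIGMOID = NS + "RECTOSIGMOID_JUNCTION"
BREAST = NS + "C12971"
LOQ_BREAST = NS + "LOQ_BREAST"
SKIN = NS + "SKIN"
EPIDERMIS = NS + "EPIDERMIS"
LANGERHANS_CELL = NS + "LANGERHANS_CELL"
BIRBECK_GRANULE = NS + "BIRBECK_GRANULE"
SOFT_PALATE = NS + "SOFT_PALATE"

# -- neoplasm ids -------------------------------------------------------
NEOPLASM_ROOT = NS + "NEOPLASM"
MALIGNANT_NEOPLASM = NS + "MALIGNANT_NEOPLASM"
BENIGN_NEOPLASM = NS + "BENIGN_NEOPLASM"
C9335 = NS + "C9335"  # Malignant Breast Neoplasm
C9329 = NS + "C9329"  # Malignant Cecum Neoplasm
C3641 = NS + "C3641"  # Stage 0 Breast Cancer
MALIGNANT_COLON_NEOPLASM = NS + "MALIGNANT_COLON_NEOPLASM"
MALIGNANT_RSJ_NEOPLASM = NS + "MALIGNANT_RSJ_NEOPLASM"
MALIGNANT_SOFT_PALATE_NEOPLASM = NS + "MALIGNANT_SOFT_PALATE_NEOPLASM"
ADENOCARCINOMA = NS + "ADENOCARCINOMA"
BREAST_ADENOCARCINOMA = NS + "BREAST_ADENOCARCINOMA"
LOQ_ADENOCARCINOMA = NS + "LOQ_BREAST_ADENOCARCINOMA"
CECUM_ADENOCARCINOMA = NS + "CECUM_ADENOCARCINOMA"
COLON_ADENOCARCINOMA = NS + "COLON_ADENOCARCINOMA"
COLORECTAL_ADENOCARCINOMA = NS + "COLORECTAL_ADENOCARCINOMA"
CARCINOMA = NS + "CARCINOMA"
CARCINOMA_IN_SITU = NS + "CARCINOMA_IN_SITU"
INVASIVE_DUCTAL_CARCINOMA = NS + "INVASIVE_DUCTAL_CARCINOMA"
HEMANGIOMA = NS + "HEMANGIOMA"
CAVERNOUS_HEMANGIOMA = NS + "CAVERNOUS_HEMANGIOMA"
COLON_CAVERNOUS_HEMANGIOMA = NS + "COLON_CAVERNOUS_HEMANGIOMA"


@dataclass
class FixtureBundle:
    onto: SourceOntology
    icd10: list[tuple[str, str]] = field(default_factory=list)  # (code, label)
    icdo3_topo: list[tuple[str, str]] = field(default_factory=list)
    icdo3_morph: list[tuple[str, str]] = field(default_factory=list)
    crosswalk: list[CuiMapRecord] = field(default_factory=list)
    gold: list[tuple[str, str, str]] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def crosswalk_table(self) -> CuiCrosswalk:
        return CuiCrosswalk(self.crosswalk)


def _concept(onto, cid, label, axis):
    onto.concepts[cid] = Concept(cid, label, axis)


def build_example_fixture(*, verify: bool = True) -> FixtureBundle:
    """The deterministic worked-example bundle (see module docstring)."""
    onto = SourceOntology()
    A, N = Axis.ANATOMY, Axis.NEOPLASM
    PHYS, LOC = RoleKind.PART_PHYSICAL, RoleKind.PART_LOCATION

    for cid, label in [
        (ANATOMIC_ROOT, "Anatomic Structure, System, or Substance"),
        (GI_SYSTEM, "Gastrointestinal System"),
        (INTESTINE, "Intestine"),
        (LARGE_INTESTINE, "Large Intestine"),
        (CECUM, "Cecum"),
        (COLON, "Colon"),
        (COLORECTAL, "Colorectal Region"),
        (RECTOSIGMOID, "Rectosigmoid Junction"),
        (BREAST, "Breast"),
        (LOQ_BREAST, "Lower Outer Quadrant of the Breast"),
        (SKIN, "Skin"),
        (EPIDERMIS, "Epidermis"),
        (LANGERHANS_CELL, "Langerhans Cell"),
        (BIRBECK_GRANULE, "Birbeck Granule"),
        (SOFT_PALATE, "Soft Palate"),
    ]:
        _concept(onto, cid, label, A)

    onto.is_a_edges += [
        (GI_SYSTEM, ANATOMIC_ROOT),
        (BREAST, ANATOMIC_ROOT),
        (SKIN, ANATOMIC_ROOT),
        (SOFT_PALATE, ANATOMIC_ROOT),
    ]
    onto.part_edges += [
        (INTESTINE, GI_SYSTEM, PHYS),
        (LARGE_INTESTINE, INTESTINE, PHYS),
        (CECUM, LARGE_INTESTINE, PHYS),
        (COLON, LARGE_INTESTINE, PHYS),
        (COLORECTAL, LARGE_INTESTINE, LOC),
        (RECTOSIGMOID, COLORECTAL, PHYS),
        (LOQ_BREAST, BREAST, PHYS),
        (EPIDERMIS, SKIN, PHYS),
        (LANGERHANS_CELL, EPIDERMIS, PHYS),
        (BIRBECK_GRANULE, LANGERHANS_CELL, PHYS),
    ]

    for cid, label in [
        (NEOPLASM_ROOT, "Neoplasm"),
        (MALIGNANT_NEOPLASM, "Malignant Neoplasm"),
        (BENIGN_NEOPLASM, "Benign Neoplasm"),
        (C9335, "Malignant Breast Neoplasm"),
        (C9329, "Malignant Cecum Neoplasm"),
        (C3641, "Stage 0 Breast Cancer"),
        (MALIGNANT_COLON_NEOPLASM, "Malignant Colon Neoplasm"),
        (MALIGNANT_RSJ_NEOPLASM, "Malignant Rectosigmoid Junction Neoplasm"),
        (MALIGNANT_SOFT_PALATE_NEOPLASM, "Malignant Soft Palate Neoplasm"),
        (ADENOCARCINOMA, "Adenocarcinoma"),
        (BREAST_ADENOCARCINOMA, "Breast Adenocarcinoma"),
        (LOQ_ADENOCARCINOMA, "Adenocarcinoma of the Lower Outer Quadrant of the Breast"),
        (CECUM_ADENOCARCINOMA, "Cecum Adenocarcinoma"),
        (COLON_ADENOCARCINOMA, "Colon Adenocarcinoma"),
        (COLORECTAL_ADENOCARCINOMA, "Colorectal Adenocarcinoma"),
        (CARCINOMA, "Carcinoma"),
        (CARCINOMA_IN_SITU, "Carcinoma In Situ"),
        (INVASIVE_DUCTAL_CARCINOMA, "Invasive Ductal Carcinoma, Not Otherwise Specified"),
        (HEMANGIOMA, "Hemangioma"),
        (CAVERNOUS_HEMANGIOMA, "Cavernous Hemangioma"),
        (COLON_CAVERNOUS_HEMANGIOMA, "Colon Cavernous Hemangioma"),
    ]:
        _concept(onto, cid, label, N)

    onto.is_a_edges += [
        (MALIGNANT_NEOPLASM, NEOPLASM_ROOT),
        (BENIGN_NEOPLASM, NEOPLASM_ROOT),
        (C9335, MALIGNANT_NEOPLASM),
        (C9329, MALIGNANT_NEOPLASM),
        (MALIGNANT_COLON_NEOPLASM, MALIGNANT_NEOPLASM),
        (MALIGNANT_RSJ_NEOPLASM, MALIGNANT_NEOPLASM),
        (MALIGNANT_SOFT_PALATE_NEOPLASM, MALIGNANT_NEOPLASM),
        (ADENOCARCINOMA, MALIGNANT_NEOPLASM),
        (CARCINOMA, MALIGNANT_NEOPLASM),
        (CARCINOMA_IN_SITU, CARCINOMA),
        (C3641, CARCINOMA_IN_SITU),
        (BREAST_ADENOCARCINOMA, ADENOCARCINOMA),
        (BREAST_ADENOCARCINOMA, C9335),
        (LOQ_ADENOCARCINOMA, BREAST_ADENOCARCINOMA),
        (CECUM_ADENOCARCINOMA, ADENOCARCINOMA),
        (CECUM_ADENOCARCINOMA, C9329),
        (COLON_ADENOCARCINOMA, ADENOCARCINOMA),
        (COLORECTAL_ADENOCARCINOMA, ADENOCARCINOMA),
        (INVASIVE_DUCTAL_CARCINOMA, CARCINOMA),
        (HEMANGIOMA, BENIGN_NEOPLASM),
        (CAVERNOUS_HEMANGIOMA, HEMANGIOMA),
        (COLON_CAVERNOUS_HEMANGIOMA, CAVERNOUS_HEMANGIOMA),
    ]

    onto.site_fillers = {
        C9335: {BREAST},
        C9329: {GI_SYSTEM, CECUM, COLON, INTESTINE, COLORECTAL},
        C3641: {BREAST},
        MALIGNANT_COLON_NEOPLASM: {COLON},
        MALIGNANT_RSJ_NEOPLASM: {RECTOSIGMOID},
        MALIGNANT_SOFT_PALATE_NEOPLASM: {SOFT_PALATE},
        BREAST_ADENOCARCINOMA: {BREAST},
        LOQ_ADENOCARCINOMA: {LOQ_BREAST},
        CECUM_ADENOCARCINOMA: {CECUM},
        COLON_ADENOCARCINOMA: {COLON},
        COLORECTAL_ADENOCARCINOMA: {COLORECTAL},
        INVASIVE_DUCTAL_CARCINOMA: {BREAST},
        COLON_CAVERNOUS_HEMANGIOMA: {COLON, COLORECTAL},
    }
    onto.morph_annotations = {
        ADENOCARCINOMA: {"8140/3"},
        CARCINOMA: {"8010/3"},  # Epithelioma, NOS (invasive)
        CARCINOMA_IN_SITU: {"8010/2"},  # Intraepithelial carcinoma, NOS
        INVASIVE_DUCTAL_CARCINOMA: {"8500/3", "8521/3"},
        HEMANGIOMA: {"9120/0"},
        CAVERNOUS_HEMANGIOMA: {"9121/0"},
    }

    bundle = FixtureBundle(onto=onto)
    bundle.icd10 = [
        ("C18.0", "Malignant neoplasm: Caecum"),
        ("C18.9", "Malignant neoplasm: Colon, unspecified"),
        ("C19.9", "Malignant neoplasm of rectosigmoid junction"),
        ("C50.9", "Malignant neoplasm of breast, unspecified"),
        ("D05", "Carcinoma in situ of breast"),
        ("C00.1", "Malignant neoplasm: External lower lip"),
        ("D40", "Neoplasm of uncertain behaviour of male genital organs"),
        ("C78.0", "Secondary malignant neoplasm of lung"),
    ]
    bundle.icdo3_topo = [
        ("C18.0", "Cecum"),
        ("C18.8", "Overlapping lesion of colon"),
        ("C18.9", "Colon, NOS"),
        ("C50.5", "Lower-outer quadrant of breast"),
        ("C50.9", "Breast, NOS"),
        ("C05.1", "Soft palate, NOS"),
        ("C76.0", "Head, face or neck, NOS"),
    ]
    bundle.icdo3_morph = [
        ("8140/3", "Adenocarcinoma, NOS"),
        ("8010/2", "Intraepithelial carcinoma, NOS"),
        ("8010/3", "Epithelioma, NOS"),
        ("8500/3", "Infiltrating duct carcinoma, NOS"),
        ("8521/3", "Infiltrating ductular carcinoma"),
        ("9120/0", "Hemangioma, NOS"),
        ("9121/0", "Cavernous hemangioma"),
        ("9999/3", "No such morphology"),
    ]

    def xw(cui: str, sab: str, code: str) -> CuiMapRecord:
        return CuiMapRecord(cui, sab, code)

    bundle.crosswalk = [
        xw("CUI0001", "ICD10", "C50.9"), xw("CUI0001", "NCI", "C9335"),
        xw("CUI0002", "ICD10", "C18.0"), xw("CUI0002", "NCI", "C9329"),
        xw("CUI0003", "ICD10", "D05"), xw("CUI0003", "NCI", "C3641"),
        xw("CUI0004", "ICD10", "C19.9"), xw("CUI0004", "NCI", "MALIGNANT_RSJ_NEOPLASM"),
        xw("CUI0005", "ICD10", "C18.9"), xw("CUI0005", "NCI", "MALIGNANT_COLON_NEOPLASM"),
        xw("CUI0006", "ICDO3", "C50.5"), xw("CUI0006", "NCI", "LOQ_BREAST"),
        xw("CUI0007", "ICDO3", "C18.9"), xw("CUI0007", "NCI", "COLON"),
        xw("CUI0008", "ICDO3", "C18.0"), xw("CUI0008", "NCI", "CECUM"),
        xw("CUI0009", "ICDO3", "C05.1"), xw("CUI0009", "NCI", "MALIGNANT_SOFT_PALATE_NEOPLASM"),
        xw("CUI0010", "ICDO3", "C50.9"), xw("CUI0010", "NCI", "C12971"),
        # an overlapping-lesion topography grouped with two incomparable
        # anatomy concepts under two CUIs (one-to-many binding)
        xw("CUI0011", "ICDO3", "C18.8"), xw("CUI0011", "NCI", "COLON"),
        xw("CUI0012", "ICDO3", "C18.8"), xw("CUI0012", "NCI", "COLORECTAL_REGION"),
    ]
    bundle.gold = [
        ("C18.0", "8140/3", "C18.0"),
        ("C18.8", "8140/3", "C18.0"),
        ("C18.9", "8140/3", "C18.9"),
        ("C50.9", "8140/3", "C50.9"),
        ("C50.5", "8140/3", "C50.9"),
        ("C50.9", "8010/2", "D05"),
        ("C50.9", "8521/6", "C78.0"),  # out of scope: metastatic behavior
    ]

    MP = "MALIGNANT_PRIMARY"
    bundle.truth = {
        "icd10_direct": {
            "C18.0": {(MP, CECUM), (MP, COLON), (MP, COLORECTAL)},
            "C50.9": {(MP, BREAST)},
            "D05": {("8010/2", BREAST), ("8010/3", BREAST)},
            "C19.9": {(MP, COLORECTAL)},
            "C18.9": {(MP, COLON)},
        },
        "icd10_status": {"C00.1": "UNMAPPED", "D40": "EXCLUDED_SCOPE",
                         "C78.0": "EXCLUDED_SCOPE"},
        "topo_direct": {"C50.5": {LOQ_BREAST}, "C18.9": {COLON}, "C18.0": {CECUM},
                        "C18.8": {COLON, COLORECTAL}},
        "topo_status": {"C05.1": "NON_ANATOMY_ONLY", "C76.0": "UNMAPPED"},
        "direct_dx": {
            COLON_CAVERNOUS_HEMANGIOMA: {
                ("9121/0", COLON), ("9121/0", COLORECTAL),
                ("9120/0", COLON), ("9120/0", COLORECTAL),
            },
        },
        "behavior_conflicts": {"D05"},
    }
    if verify:
        _verify_against_oracle(bundle)
    return bundle


def _verify_against_oracle(bundle: FixtureBundle) -> None:
    """Replay the truth tables on the independent saturation oracle."""
    oracle = brute_force_oracle(bundle.onto)
    crosswalk = bundle.crosswalk_table()
    # direct diagnosis classes of concepts named in the truth table
    for concept, expected in bundle.truth.get("direct_dx", {}).items():
        got = set(oracle.direct_types(concept))
        if got != expected:
            raise AssertionError(
                f"fixture truth mismatch for {concept}: oracle {got} != {expected}"
            )
    # worked-example reachability facts
    for s, t, expected in [
        (CECUM, LARGE_INTESTINE, True),
        (BIRBECK_GRANULE, SKIN, True),
        (COLON, COLORECTAL, False),
    ]:
        if oracle.anat_leq(s, t) is not expected:
            raise AssertionError(f"fixture reachability {s} <= {t} != {expected}")
    # ICD-10 truth via the oracle's satisfied sets
    for code, expected in bundle.truth["icd10_direct"].items():
        _, targets = crosswalk.source_targets(code, "ICD10")
        behavior = "MALIGNANT_PRIMARY" if code.startswith("C") else "IN_SITU"
        satisfied = set()
        for concept in targets:
            if concept not in oracle.inherited_morphs:
                continue
            morphs = set(oracle.inherited_morphs[concept]) | {behavior}
            for (m, t) in oracle.retained:
                if any(oracle.morph_leq(mc, m) for mc in morphs) and any(
                    oracle.anat_leq(s, t) for s in oracle.inherited_sites[concept]
                ):
                    satisfied.add((m, t))
        minimal = {
            k for k in satisfied
            if not any(j != k and oracle.dx_leq(j, k) for j in satisfied)
        }
        if minimal != expected:
            raise AssertionError(
                f"fixture truth mismatch for {code}: oracle {minimal} != {expected}"
            )


@dataclass(frozen=True)
class GenParams:
    """Knobs of the random-ontology generator (all counts >= 0)."""

    n_anatomy: int = 15
    n_neoplasm: int = 15
    n_morph: int = 8
    p_is_a: float = 0.15
    p_part: float = 0.12
    p_site: float = 0.15
    p_annot: float = 0.35
    seed: int = 0


def random_ontology(params: GenParams) -> SourceOntology:
    """Seeded random source ontology; acyclic by layered construction."""
    if min(params.n_anatomy, params.n_neoplasm, params.n_morph) < 0:
        raise ValueError("counts must be >= 0")
    rng = random.Random(params.seed)
    onto = SourceOntology()

    anatomy = [f"A:{i:03d}" for i in range(params.n_anatomy)]
    neoplasm = [f"N:{i:03d}" for i in range(params.n_neoplasm)]
    codes = []
    for i in range(params.n_morph):
        digit = rng.choice([0, 1, 2, 3, 6, 9])
        codes.append(f"{8000 + i:04d}/{digit}")

    for cid in anatomy:
        _concept(onto, cid, f"Anatomy {cid}", Axis.ANATOMY)
    for cid in neoplasm:
        _concept(onto, cid, f"Neoplasm {cid}", Axis.NEOPLASM)

    # edges point from higher index to strictly lower index: acyclic
    for ids in (anatomy, neoplasm):
        for i in range(1, len(ids)):
            for j in range(i):
                if rng.random() < params.p_is_a:
                    onto.is_a_edges.append((ids[i], ids[j]))
    for i in range(1, len(anatomy)):
        for j in range(i):
            if rng.random() < params.p_part:
                role = rng.choice([RoleKind.PART_PHYSICAL, RoleKind.PART_LOCATION])
                onto.part_edges.append((anatomy[i], anatomy[j], role))

    for cid in neoplasm:
        sites = {a for a in anatomy if rng.random() < params.p_site}
        if sites:
            onto.site_fillers[cid] = sites
        if codes and rng.random() < params.p_annot:
            k = rng.choice([1, 1, 1, 2])
            onto.morph_annotations[cid] = set(rng.sample(codes, min(k, len(codes))))
    return onto


def scale_ontology(
    n_anatomy: int,
    n_neoplasm: int,
    n_morph: int,
    seed: int = 0,
) -> SourceOntology:
    """Large sparse ontology for scale smoke runs (no truth tables).

    The anatomy graph is a random recursive tree (one parent drawn
    uniformly among earlier nodes, so expected depth is logarithmic) with a
    5% sprinkling of second parents; every anatomy node is asserted as a
    site filler of some neoplasm concept and every morphology code is
    annotated on some concept, so the collected topography and morphology
    counts equal the requested sizes exactly.
    """
    rng = random.Random(seed)
    onto = SourceOntology()
    anatomy = [f"A:{i:05d}" for i in range(n_anatomy)]
    neoplasm = [f"N:{i:05d}" for i in range(n_neoplasm)]
    codes = [f"{8000 + i:04d}/{rng.choice([0, 2, 3, 3, 3, 9])}" for i in range(n_morph)]

    for cid in anatomy:
        _concept(onto, cid, cid, Axis.ANATOMY)
    for cid in neoplasm:
        _concept(onto, cid, cid, Axis.NEOPLASM)
    for i in range(1, n_anatomy):
        parent = anatomy[rng.randrange(i)]
        role = rng.choice([RoleKind.PART_PHYSICAL, RoleKind.PART_LOCATION])
        onto.part_edges.append((anatomy[i], parent, role))
        if rng.random() < 0.05:
            onto.is_a_edges.append((anatomy[i], anatomy[rng.randrange(i)]))
    for j in range(1, n_neoplasm):
        onto.is_a_edges.append((neoplasm[j], neoplasm[rng.randrange(j)]))
    for i, site in enumerate(anatomy):
        onto.site_fillers.setdefault(neoplasm[i % n_neoplasm], set()).add(site)
    for i, code in enumerate(codes):
        onto.morph_annotations.setdefault(neoplasm[i % n_neoplasm], set()).add(code)
    return onto


def plant_gold_standard(
    model,
    bindings,
    *,
    seed: int = 0,
    n_sample: int | None = None,
) -> tuple[list[tuple[str, str, str]], dict]:
    """Sample combinations whose nearest ICD-10 code is strictly unique.

    For every bound (topography, morphology) combination the minimum
    edge distance to every bound ICD-10 code is computed; combinations with
    a unique argmin become gold rows mapping to that code.  The returned
    truth records the planted code and its winning margin per combination;
    combinations without a strict winner are skipped (logged in the truth
    under ``skipped``).
    """
    from .core import dx_subsumes, minimal_elements
    from .evaluation import rebuild_mappings
    from .terminology import satisfied_dx_of_combination
    import math

    rng = random.Random(seed)
    bound_topo = sorted(c for c, b in bindings.topo.items() if b.bound)
    bound_morph = sorted(c for c, b in bindings.morph.items() if b.bound)
    combos_all = [(t, mc) for t in bound_topo for mc in bound_morph]
    if n_sample is not None and n_sample < len(combos_all):
        combos_all = sorted(rng.sample(combos_all, n_sample))

    def leq(k1, k2):
        return dx_subsumes(model.dx.classes[k1], model.dx.classes[k2], model.axis, model.idx)

    combo_minimal = {}
    for t, mc in combos_all:
        sat = satisfied_dx_of_combination(
            bindings.topo[t], bindings.morph[mc], model.dx, model.axis, model.idx
        )
        if sat:
            combo_minimal[(t, mc)] = minimal_elements(sat, leq)
    predictions = rebuild_mappings(bindings.icd10, combo_minimal, model.dx)

    gold: list[tuple[str, str, str]] = []
    truth: dict = {"planted": {}, "skipped": []}
    for key in sorted(combo_minimal):
        pred = predictions[key]
        if len(pred.predicted) == 1 and not math.isinf(pred.distance):
            code = pred.predicted[0]
            gold.append((key[0], key[1], code))
            truth["planted"][key] = {"code": code, "distance": pred.distance}
        else:
            truth["skipped"].append(key)
    return gold, truth


def write_fixture_files(bundle: FixtureBundle, root: Path | str) -> dict[str, Path]:
    """Write the bundle to disk in the formats the ingestion modules read."""
    from .ingest import write_native_tsv

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    onto_dir = root / "ontology"
    write_native_tsv(bundle.onto, onto_dir)
    paths = {"ontology": onto_dir}

    for name, rows in [
        ("icd10.csv", bundle.icd10),
        ("icdo3_topography.csv", bundle.icdo3_topo),
        ("icdo3_morphology.csv", bundle.icdo3_morph),
    ]:
        p = root / name
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("code,label\n")
            for code, label in rows:
                fh.write(f'{code},"{label}"\n' if "," in label else f"{code},{label}\n")
        paths[name] = p

    p = root / "crosswalk.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("cui\tsab\tcode\n")
        for r in sorted(bundle.crosswalk, key=lambda r: (r.cui, r.sab, r.code)):
            fh.write(f"{r.cui}\t{r.sab}\t{r.code}\n")
    paths["crosswalk.tsv"] = p

    p = root / "seer_gold.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("topography\tmorphology\ticd10\n")
        for topo, morph, icd10 in bundle.gold:
            fh.write(f"{topo}\t{morph}\t{icd10}\n")
    paths["seer_gold.tsv"] = p
    return paths
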