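"""Terminology ingestion and instantiation of the derivative model.

ICD-O-3 morphology codes bind directly to morphology classes by their
``HHHH/B`` code.  ICD-O-3 topography codes bind through the CUI crosswalk:
the source-ontology concepts sharing a CUI with the code are looked up, the
anatomical ones kept, and the code becomes an instance of the minimal
reflexive-part classes above them.  ICD-10 codes also bind through CUIs,
but because an ICD-10 neoplasm code carries its behavior in its block
(malignant / in situ / benign), the behavior is added as an extra
morphology restriction alongside whatever the mapped concept inherits.

Inherited morphologies are deliberately NOT filtered by the ICD-10
behavior: when a mapped concept inherits both an in-situ and an invasive
code, both survive into the binding, and the contradiction is surfaced by
the audit stage rather than silently resolved here.

Scope exclusions follow the conventional ICD-10 block ranges: C77-C79
(secondary malignancies) and D37-D48 (uncertain behavior) are out of scope
by default; see ``docs/methods.md`` for the block-range discussion.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

from .core import (
    AnatomyIndex,
    BehaviorClass,
    DxLatticeError,
    SourceOntology,
    UnknownIdError,
    minimal_elements,
)
from .anatomy import RPLattice
from .diagnosis import DxLattice
from .morphology import (
    MorphologyAxis,
    RefinedConceptIndex,
    behavior_class_of,
    parse_morphology_code,
)

__all__ = [
    "System",
    "BindingStatus",
    "Excluded",
    "TerminologyCode",
    "CuiMapRecord",
    "CuiCrosswalk",
    "BindingResult",
    "read_terminology",
    "derive_icd10_behavior",
    "read_cui_map",
    "bind_topography",
    "bind_morphology",
    "bind_icd10",
    "satisfied_dx_of_combination",
    "DEFAULT_ICD10_BLOCKS",
]


class System(str, enum.Enum):
    ICD10 = "ICD10"
    ICDO3_T = "ICDO3_T"
    ICDO3_M = "ICDO3_M"


class BindingStatus(str, enum.Enum):
    BOUND = "BOUND"
    UNMAPPED = "UNMAPPED"
    NON_ANATOMY_ONLY = "NON_ANATOMY_ONLY"
    EXCLUDED_SCOPE = "EXCLUDED_SCOPE"
    NO_SITE = "NO_SITE"


@dataclass(frozen=True)
class Excluded:
    """Marker for codes outside the modelled behavior scope."""

    reason: str


#: (letter, first category, last category) -> behavior or exclusion
DEFAULT_ICD10_BLOCKS: list[tuple[str, int, int, BehaviorClass | Excluded]] = [
    ("C", 0, 76, BehaviorClass.MALIGNANT_PRIMARY),
    ("C", 77, 79, Excluded("secondary malignancy")),
    # C80 ill-defined and C81-C96 lymphoid/haematopoietic malignancies are
    # primary tumors; keeping them in scope is what lets the hematopoietic
    # stratum of the evaluation exist at all (see docs/methods.md)
    ("C", 80, 97, BehaviorClass.MALIGNANT_PRIMARY),
    ("D", 0, 9, BehaviorClass.IN_SITU),
    ("D", 10, 36, BehaviorClass.BENIGN),
    ("D", 37, 48, Excluded("uncertain or unknown behavior")),
]

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(?:\.\d{1,2})?$")


@dataclass
class TerminologyCode:
    code: str
    system: System
    label: str = ""
    behavior: BehaviorClass | Excluded | None = None
    cuis: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class CuiMapRecord:
    cui: str
    sab: str
    code: str


class CuiCrosswalk:
    """CUI-keyed join table between terminologies and the source ontology."""

    def __init__(
        self,
        records: list[CuiMapRecord],
        *,
        sab_icd10: str = "ICD10",
        sab_icdo3: str = "ICDO3",
        sab_source: str = "NCI",
        source_prefix: str = "NCIT:",
    ):
        self.records = records
        self.sab_icd10 = sab_icd10
        self.sab_icdo3 = sab_icdo3
        self.sab_source = sab_source
        self.source_prefix = source_prefix
        self._by_sab_code: dict[tuple[str, str], set[str]] = {}
        self._source_by_cui: dict[str, set[str]] = {}
        for r in records:
            self._by_sab_code.setdefault((r.sab, r.code), set()).add(r.cui)
            if r.sab == sab_source:
                self._source_by_cui.setdefault(r.cui, set()).add(r.code)

    def cuis_of(self, code: str, sab: str) -> set[str]:
        return self._by_sab_code.get((sab, code), set())

    def source_targets(self, code: str, sab: str) -> tuple[set[str], set[str]]:
        """(cuis of the code, source-ontology concept ids sharing a cui)."""
        cuis = self.cuis_of(code, sab)
        targets: set[str] = set()
        for cui in cuis:
            for src_code in self._source_by_cui.get(cui, ()):
                targets.add(self.source_prefix + src_code)
        return cuis, targets


@dataclass
class BindingResult:
    """Outcome of instantiating one terminology code.

    ``direct_classes`` holds RP base ids for topographies, morphology codes
    for morphologies, and (morphology, base) diagnosis keys for ICD-10.
    ``satisfied_classes`` (ICD-10 only) is the full upward-closed satisfied
    set inside the diagnosis lattice; ``anatomy_targets`` (topography only)
    are the mapped anatomy concepts themselves.
    """

    code: str
    system: System
    status: BindingStatus
    direct_classes: tuple = ()
    satisfied_classes: frozenset = frozenset()
    anatomy_targets: tuple = ()
    reason: str = ""

    @property
    def bound(self) -> bool:
        return self.status is BindingStatus.BOUND


def derive_icd10_behavior(
    code: str,
    blocks: list[tuple[str, int, int, BehaviorClass | Excluded]] | None = None,
) -> BehaviorClass | Excluded:
    """Behavior of an ICD-10 neoplasm code from its block range."""
    blocks = blocks if blocks is not None else DEFAULT_ICD10_BLOCKS
    m = _ICD10_RE.match(code.strip())
    if not m:
        return Excluded(f"not an ICD-10 code: {code!r}")
    letter, category = m.group(1), int(m.group(2))
    for b_letter, lo, hi, outcome in blocks:
        if letter == b_letter and lo <= category <= hi:
            return outcome
    return Excluded(f"outside configured neoplasm blocks: {code}")


def read_terminology(path: Path | str, system: System) -> list[TerminologyCode]:
    """Read a ``code,label`` CSV/TSV; dedupe; populate behavior."""
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out: list[TerminologyCode] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["code", "label"]:
            raise DxLatticeError(f"{path}: expected 'code,label' header")
        for i, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise DxLatticeError(f"{path}:{i}: expected code and label fields")
            code, label = row[0].strip(), row[1].strip()
            if code in seen:
                continue  # duplicate-code rows are collapsed
            seen.add(code)
            behavior: BehaviorClass | Excluded | None = None
            if system is System.ICD10:
                behavior = derive_icd10_behavior(code)
            elif system is System.ICDO3_M:
                _, digit = parse_morphology_code(code)
                behavior = behavior_class_of(digit)
            out.append(TerminologyCode(code, system, label, behavior))
    return out


def read_cui_map(
    path: Path | str,
    dialect: str = "TSV",
    *,
    rrf_columns: tuple[int, int, int] = (0, 11, 13),
) -> list[CuiMapRecord]:
    """Read a crosswalk in RRF (pipe-delimited, positional columns) or TSV.

    In RRF, ``rrf_columns`` gives the positions of CUI, SAB and CODE (the
    MRCONSO defaults); remaining columns are ignored.  TSV expects a header
    with exactly ``cui  sab  code``.
    """
    path = Path(path)
    records: list[CuiMapRecord] = []
    bad = 0
    with open(path, encoding="utf-8") as fh:
        if dialect == "RRF_PIPE":
            need = max(rrf_columns) + 1
            for line in fh:
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("|")
                if len(fields) < need:
                    bad += 1
                    continue
                ci, si, ki = rrf_columns
                records.append(CuiMapRecord(fields[ci], fields[si], fields[ki]))
        elif dialect == "TSV":
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is not None and [h.strip().lower() for h in header] != ["cui", "sab", "code"]:
                raise DxLatticeError(f"{path}: expected 'cui\\tsab\\tcode' header")
            for i, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != 3:
                    bad += 1
                    continue
                records.append(CuiMapRecord(*[f.strip() for f in row]))
        else:
            raise DxLatticeError(f"unknown crosswalk dialect {dialect!r}")
    if bad:
        if bad > max(10, len(records)):
            raise DxLatticeError(f"{path}: {bad} malformed rows (threshold exceeded)")
    # (cui, sab, code) unique
    return sorted(set(records), key=lambda r: (r.cui, r.sab, r.code))


def bind_topography(
    code: str,
    crosswalk: CuiCrosswalk,
    onto: SourceOntology,
    rp: RPLattice,
    idx: AnatomyIndex,
) -> BindingResult:
    """Instantiate the reflexive-part classes of an ICD-O-3 topography code."""
    cuis, targets = crosswalk.source_targets(code, crosswalk.sab_icdo3)
    if not cuis or not targets:
        return BindingResult(code, System.ICDO3_T, BindingStatus.UNMAPPED,
                             reason="no CUI link to the source ontology")
    anatomy_targets = sorted(t for t in targets if t in idx)
    if not anatomy_targets:
        return BindingResult(
            code, System.ICDO3_T, BindingStatus.NON_ANATOMY_ONLY,
            reason=f"all mapped concepts outside the anatomy axis: {sorted(targets)}",
        )
    bases: set[str] = set()
    for target in anatomy_targets:
        in_lattice = [t for t in idx.up_set(target) if t in rp]
        bases.update(minimal_elements(in_lattice, idx.leq))
    direct = tuple(minimal_elements(bases, idx.leq))
    return BindingResult(
        code, System.ICDO3_T, BindingStatus.BOUND,
        direct_classes=direct, anatomy_targets=tuple(anatomy_targets),
    )


def bind_morphology(code: str, axis: MorphologyAxis) -> BindingResult:
    """Instantiate the morphology class carrying the same ``HHHH/B`` code."""
    parse_morphology_code(code)  # propagate format errors
    if code in axis.specific:
        return BindingResult(code, System.ICDO3_M, BindingStatus.BOUND,
                             direct_classes=(code,))
    return BindingResult(code, System.ICDO3_M, BindingStatus.UNMAPPED,
                         reason="no morphology class with this code")


def _icd10_satisfied(
    concept: str,
    behavior: BehaviorClass,
    lattice: DxLattice,
    refined: RefinedConceptIndex,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
) -> set[tuple[str, str]]:
    morph_up: set[str] = set()
    for mc in refined.inherited_morphs.get(concept, frozenset()):
        morph_up |= axis.up_set(mc)
    morph_up |= axis.up_set(behavior.value)
    morph_up.discard(axis.root_id)
    site_up: set[str] = set()
    for s in refined.inherited_sites.get(concept, frozenset()):
        if s in idx:
            site_up |= idx.up_set(s)
    return {
        (m, t) for m in morph_up for t in site_up if (m, t) in lattice
    }


def bind_icd10(
    code_or_tc: str | TerminologyCode,
    crosswalk: CuiCrosswalk,
    onto: SourceOntology,
    refined: RefinedConceptIndex,
    lattice: DxLattice,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
) -> BindingResult:
    """Instantiate diagnosis classes for an ICD-10 neoplasm code.

    The mapped concept's definition is restricted by the code's block
    behavior (an extra morphology restriction) and by the concept's
    inherited primary sites; the code becomes an instance of the minimal
    retained diagnosis classes satisfying both.
    """
    if isinstance(code_or_tc, TerminologyCode):
        code, behavior = code_or_tc.code, code_or_tc.behavior
    else:
        code, behavior = code_or_tc, derive_icd10_behavior(code_or_tc)
    if behavior is None or isinstance(behavior, Excluded):
        reason = behavior.reason if isinstance(behavior, Excluded) else "no behavior"
        return BindingResult(code, System.ICD10, BindingStatus.EXCLUDED_SCOPE, reason=reason)
    cuis, targets = crosswalk.source_targets(code, crosswalk.sab_icd10)
    if not cuis or not targets:
        return BindingResult(code, System.ICD10, BindingStatus.UNMAPPED,
                             reason="no CUI link to the source ontology")
    satisfied: set[tuple[str, str]] = set()
    any_site = False
    for concept in sorted(targets):
        if concept not in refined:
            continue
        if refined.inherited_sites.get(concept):
            any_site = True
        satisfied |= _icd10_satisfied(concept, behavior, lattice, refined, axis, idx)
    if not satisfied:
        reason = (
            "no mapped concept carries a primary site" if not any_site
            else "no retained diagnosis class matched"
        )
        return BindingResult(code, System.ICD10, BindingStatus.NO_SITE, reason=reason)

    def leq(k1, k2):
        from .core import dx_subsumes  # local to avoid re-import noise

        return dx_subsumes(lattice.classes[k1], lattice.classes[k2], axis, idx)

    direct = tuple(minimal_elements(satisfied, leq))
    return BindingResult(
        code, System.ICD10, BindingStatus.BOUND,
        direct_classes=direct, satisfied_classes=frozenset(satisfied),
    )


def satisfied_dx_of_combination(
    topo: BindingResult,
    morph: BindingResult,
    lattice: DxLattice,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
) -> set[tuple[str, str]]:
    """All lattice classes satisfied by a topography-morphology combination.

    The combination instantiates D(m, t) whenever its morphology class is
    subsumed by m and one of its mapped anatomy concepts lies inside t.
    The result is upward-closed within the lattice (satisfied, not direct).
    """
    if not (topo.bound and morph.bound):
        raise DxLatticeError(
            f"combination requires two BOUND inputs, got {topo.status}/{morph.status}"
        )
    morph_up = axis.up_set(morph.direct_classes[0])
    site_up: set[str] = set()
    for a in topo.anatomy_targets:
        site_up |= idx.up_set(a)
    return {(m, t) for m in morph_up for t in site_up if (m, t) in lattice}
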