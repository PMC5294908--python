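"""Auditing the instantiated model for source-ontology inconsistencies.

A code that instantiates several incomparable diagnosis classes is a
symptom worth reviewing: either the source ontology asserts several
genuinely incomparable primary sites for the mapped concept, or an is_a
link is standing in for something weaker (is_a overloading), or a
part-whole link is missing between the sites.  Two concrete detectors are
provided on top of the raw multi-instantiation counts:

* behavior conflicts — a code whose direct classes carry two different
  behavior classes (e.g. one in-situ and one invasive morphology); a tumor
  cannot have both behaviors at once, so one of the inherited morphology
  annotations is suspect;
* incomparable sites — a code whose direct classes sit on mutually
  incomparable topographies; the base pairs are reported as candidate
  missing part-of links or is_a overload evidence.

No threshold separates overloading from legitimate multiple sites; every
multi-branch case is reported uniformly and left to human review.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import AnatomyIndex, BehaviorClass
from .diagnosis import DxLattice
from .morphology import MorphologyAxis
from .terminology import BindingResult, BindingStatus, System

__all__ = [
    "ConflictKind",
    "ConflictFlag",
    "AuditCategory",
    "AuditReport",
    "multi_instantiation_report",
    "behavior_conflicts",
    "inconsistency_hypotheses",
    "write_audit_tsv",
    "write_audit_json",
]


class ConflictKind(str, enum.Enum):
    BEHAVIOR_CONFLICT = "BEHAVIOR_CONFLICT"
    INCOMPARABLE_SITES = "INCOMPARABLE_SITES"


@dataclass(frozen=True)
class ConflictFlag:
    code: str
    kind: ConflictKind
    evidence: tuple  # pair(s) of class ids / base ids


@dataclass
class AuditCategory:
    name: str
    n_bound: int = 0
    n_multi: int = 0

    @property
    def pct_multi(self) -> float:
        return 100.0 * self.n_multi / self.n_bound if self.n_bound else 0.0


@dataclass
class AuditReport:
    categories: list[AuditCategory] = field(default_factory=list)
    details: list[dict] = field(default_factory=list)
    flags: list[ConflictFlag] = field(default_factory=list)

    def category(self, name: str) -> AuditCategory:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(name)


_ICD10_SUBCATS = {
    BehaviorClass.BENIGN: "ICD-10 Benign",
    BehaviorClass.IN_SITU: "ICD-10 In situ",
    BehaviorClass.MALIGNANT_PRIMARY: "ICD-10 Malignant",
}


def multi_instantiation_report(
    bindings: list[BindingResult],
    behaviors: dict[str, BehaviorClass] | None = None,
) -> AuditReport:
    """Count codes instantiating multiple classes, per category.

    ``behaviors`` maps ICD-10 codes to their block behavior for the
    benign / in-situ / malignant sub-rows; when omitted the sub-rows are
    derived from the default block ranges.
    """
    from .terminology import derive_icd10_behavior, Excluded

    cats = {
        name: AuditCategory(name)
        for name in (
            "ICD-O-3 Topographies", "ICD-O-3 Morphologies", "ICD-10",
            "ICD-10 Benign", "ICD-10 In situ", "ICD-10 Malignant",
        )
    }
    report = AuditReport(categories=list(cats.values()))
    for b in sorted(bindings, key=lambda b: (b.system.value, b.code)):
        if b.status is not BindingStatus.BOUND:
            continue
        multi = len(b.direct_classes) > 1
        names: list[str] = []
        if b.system is System.ICDO3_T:
            names = ["ICD-O-3 Topographies"]
        elif b.system is System.ICDO3_M:
            names = ["ICD-O-3 Morphologies"]
        else:
            names = ["ICD-10"]
            behavior = (behaviors or {}).get(b.code)
            if behavior is None:
                derived = derive_icd10_behavior(b.code)
                behavior = None if isinstance(derived, Excluded) else derived
            sub = _ICD10_SUBCATS.get(behavior)
            if sub:
                names.append(sub)
        for name in names:
            cats[name].n_bound += 1
            if multi:
                cats[name].n_multi += 1
        report.details.append(
            {
                "code": b.code,
                "system": b.system.value,
                "n_classes": len(b.direct_classes),
                "classes": [str(c) for c in b.direct_classes],
            }
        )
    return report


def behavior_conflicts(
    bindings: list[BindingResult],
    lattice: DxLattice,
    axis: MorphologyAxis,
) -> list[ConflictFlag]:
    """Codes whose direct diagnosis classes span several behavior classes."""
    flags: list[ConflictFlag] = []
    for b in sorted(bindings, key=lambda b: b.code):
        if b.system is not System.ICD10 or not b.bound:
            continue
        by_behavior: dict[BehaviorClass, tuple[str, str]] = {}
        for key in b.direct_classes:
            behavior = axis.behavior_of(key[0])
            if behavior is not None and behavior not in by_behavior:
                by_behavior[behavior] = key
        if len(by_behavior) >= 2:
            evidence = tuple(
                by_behavior[beh] for beh in sorted(by_behavior, key=lambda x: x.value)
            )
            flags.append(ConflictFlag(b.code, ConflictKind.BEHAVIOR_CONFLICT, evidence))
    return flags


def _bases_of(binding: BindingResult) -> list[str]:
    if binding.system is System.ICDO3_T:
        return sorted(binding.direct_classes)
    if binding.system is System.ICD10:
        return sorted({key[1] for key in binding.direct_classes})
    return []


def inconsistency_hypotheses(
    bindings: list[BindingResult], anat: AnatomyIndex
) -> list[ConflictFlag]:
    """Suggest relation reviews for multi-branch codes on incomparable sites.

    For every bound code whose direct classes rest on two or more mutually
    incomparable anatomy bases, the incomparable base pairs are emitted as
    candidate missing part-of links (or evidence of is_a overloading in the
    concept that asserted both sites).
    """
    out: list[ConflictFlag] = []
    for b in sorted(bindings, key=lambda b: b.code):
        if not b.bound:
            continue
        bases = _bases_of(b)
        if len(bases) < 2:
            continue
        pairs = tuple(
            (s, t)
            for i, s in enumerate(bases)
            for t in bases[i + 1:]
            if not anat.leq(s, t) and not anat.leq(t, s)
        )
        if pairs:
            out.append(ConflictFlag(b.code, ConflictKind.INCOMPARABLE_SITES, pairs))
    return out


def write_audit_tsv(report: AuditReport, path: Path | str, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("category\tn\tn_multi\tpct\n")
        for cat in report.categories:
            fh.write(f"{cat.name}\t{cat.n_bound}\t{cat.n_multi}\t{cat.pct_multi:.1f}\n")


def write_audit_json(report: AuditReport, path: Path | str, header: str = "") -> None:
    payload = {
        "meta": header,
        "categories": [
            {"category": c.name, "n": c.n_bound, "n_multi": c.n_multi,
             "pct": round(c.pct_multi, 1)}
            for c in report.categories
        ],
        "details": report.details,
        "flags": [
            {"code": f.code, "kind": f.kind.value, "evidence": [list(map(str, e)) if isinstance(e, tuple) else str(e) for e in f.evidence]}
            for f in report.flags
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
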