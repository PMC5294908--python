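"""Evaluation against a SEER-style conversion gold standard.

The gold standard is a table of (ICD-O-3 topography, ICD-O-3 morphology,
ICD-10) triples.  Two questions are asked of every evaluable triple (one
where all three codes instantiate the model):

1. relatedness — do the ICD-10 code and the topography-morphology
   combination instantiate at least one common diagnosis class?  The
   minimal common classes ("branches") are reported; more than one branch
   signals the multi-instantiation situations the audit stage flags.
2. rebuildability — running a nearest-neighbour mapping (minimum
   hierarchical edge-based distance on the diagnosis Hasse diagram between
   the code's direct classes and the combination's minimal satisfied
   classes), is the gold ICD-10 code among the predicted codes?  Ties are
   kept, not broken: a combination predicting several codes at the same
   minimum distance is counted as a non-unique mapping.

Distances are computed on the diagnosis lattice only (up-steps to a common
ancestor on the Hasse diagram); the common-ancestor distance is symmetric
with d(x, x) = 0 but is not asserted to satisfy the triangle inequality.
"""

from __future__ import annotations

import csv
import enum
import json
import math
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

from .core import AnatomyIndex, UnknownIdError, dx_subsumes, minimal_elements
from .diagnosis import DxLattice
from .morphology import MorphologyAxis, parse_morphology_code
from .terminology import BindingResult, derive_icd10_behavior, Excluded

__all__ = [
    "Stratum",
    "GoldMapping",
    "EvalCounts",
    "EvalReport",
    "PredictedMapping",
    "NOT_EVALUABLE",
    "read_seer_conversion",
    "shared_branches",
    "dx_edge_distance",
    "rebuild_mappings",
    "evaluate",
    "write_eval_tsv",
    "write_eval_json",
]


class Stratum(str, enum.Enum):
    HEMATOPOIETIC = "HEMATOPOIETIC"
    SOLID = "SOLID"


#: default hematopoietic ranges: ICD-10 C81-C96, morphology histology 9590-9993
HEME_ICD10_RANGE = (81, 96)
HEME_MORPH_RANGE = (9590, 9993)

NOT_EVALUABLE = "NOT_EVALUABLE"

_ICD10_CAT_RE = re.compile(r"^([A-Z])(\d{2})")


@dataclass(frozen=True)
class GoldMapping:
    topo_code: str
    morph_code: str
    icd10_code: str
    stratum: Stratum


@dataclass
class PredictedMapping:
    topo_code: str
    morph_code: str
    predicted: tuple[str, ...]  # all argmin ICD-10 codes, ties kept
    distance: float  # the minimum distance, inf when unpredicted


@dataclass
class EvalCounts:
    n_evaluable: int = 0
    n_related: int = 0
    n_multibranch: int = 0
    n_rebuilt: int = 0
    n_nonunique: int = 0


@dataclass
class EvalReport:
    total: EvalCounts = field(default_factory=EvalCounts)
    by_stratum: dict[Stratum, EvalCounts] = field(
        default_factory=lambda: {s: EvalCounts() for s in Stratum}
    )
    n_not_evaluable: int = 0


def _stratum_of(icd10_code: str, morph_code: str) -> Stratum:
    m = _ICD10_CAT_RE.match(icd10_code)
    if m and m.group(1) == "C" and HEME_ICD10_RANGE[0] <= int(m.group(2)) <= HEME_ICD10_RANGE[1]:
        return Stratum.HEMATOPOIETIC
    hist, _ = parse_morphology_code(morph_code)
    if HEME_MORPH_RANGE[0] <= int(hist) <= HEME_MORPH_RANGE[1]:
        return Stratum.HEMATOPOIETIC
    return Stratum.SOLID


def read_seer_conversion(path: Path | str) -> tuple[list[GoldMapping], int]:
    """Read the 3-column gold TSV; drop out-of-scope rows.

    Rows whose morphology behavior is metastatic (/6) or uncertain (/1, /9)
    or whose ICD-10 code falls in an excluded block are dropped; the count
    of dropped rows is returned alongside the retained mappings.
    """
    path = Path(path)
    gold: list[GoldMapping] = []
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 3:
            raise ValueError(f"{path}: expected 3-column TSV with header")
        for i, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{i}: expected 3 fields")
            topo, morph, icd10 = (f.strip() for f in row[:3])
            _, digit = parse_morphology_code(morph)
            if digit in (1, 6, 9):
                dropped += 1
                continue
            if isinstance(derive_icd10_behavior(icd10), Excluded):
                dropped += 1
                continue
            gold.append(GoldMapping(topo, morph, icd10, _stratum_of(icd10, morph)))
    return gold, dropped


def shared_branches(
    icd10_binding: BindingResult,
    combo_satisfied: set[tuple[str, str]],
    lattice: DxLattice,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
):
    """Minimal common diagnosis classes of a code and a combination.

    Returns ``NOT_EVALUABLE`` when the ICD-10 side is unbound; otherwise the
    antichain of minimal elements of the intersection of the two satisfied
    sets (possibly empty).
    """
    if not icd10_binding.bound:
        return NOT_EVALUABLE
    common = set(icd10_binding.satisfied_classes) & set(combo_satisfied)

    def leq(k1, k2):
        return dx_subsumes(lattice.classes[k1], lattice.classes[k2], axis, idx)

    return minimal_elements(common, leq)


def _up_distances(lattice: DxLattice, start: tuple[str, str]) -> dict[tuple[str, str], int]:
    """BFS distance (in up-steps on the Hasse diagram) to every ancestor."""
    parents: dict = {}
    for sub, sup in lattice.direct_edges:
        parents.setdefault(sub, []).append(sup)
    dist = {start: 0}
    q = deque([start])
    while q:
        node = q.popleft()
        for p in parents.get(node, ()):
            if p not in dist:
                dist[p] = dist[node] + 1
                q.append(p)
    return dist


def dx_edge_distance(
    k1: tuple[str, str], k2: tuple[str, str], lattice: DxLattice
) -> float:
    """Minimum common-ancestor edge distance between two diagnosis classes."""
    for k in (k1, k2):
        if k not in lattice:
            raise UnknownIdError(str(k), "diagnosis lattice")
    up1 = _up_distances(lattice, k1)
    up2 = _up_distances(lattice, k2)
    common = set(up1) & set(up2)
    if not common:
        return math.inf
    return min(up1[z] + up2[z] for z in common)


def rebuild_mappings(
    icd10_bindings: dict[str, BindingResult],
    combos: dict[tuple[str, str], list[tuple[str, str]]],
    lattice: DxLattice,
) -> dict[tuple[str, str], PredictedMapping]:
    """Nearest-code prediction for each combination, ties kept.

    ``combos`` maps (topography code, morphology code) to the combination's
    minimal satisfied diagnosis classes.  The distance from a combination to
    an ICD-10 code is the minimum pairwise edge distance between the code's
    direct classes and the combination's minimal classes; all codes at the
    overall minimum are predicted.  Combinations at infinite distance from
    every code stay unpredicted.
    """
    up_cache: dict[tuple[str, str], dict] = {}

    def up(k):
        if k not in up_cache:
            up_cache[k] = _up_distances(lattice, k)
        return up_cache[k]

    out: dict[tuple[str, str], PredictedMapping] = {}
    bound_codes = sorted(c for c, b in icd10_bindings.items() if b.bound)
    for combo_key in sorted(combos):
        combo_classes = combos[combo_key]
        best = math.inf
        argmin: list[str] = []
        for code in bound_codes:
            d_code = math.inf
            for ck in icd10_bindings[code].direct_classes:
                up_c = up(ck)
                for mk in combo_classes:
                    up_m = up(mk)
                    common = set(up_c) & set(up_m)
                    if common:
                        d = min(up_c[z] + up_m[z] for z in common)
                        d_code = min(d_code, d)
            if d_code < best:
                best, argmin = d_code, [code]
            elif d_code == best and not math.isinf(d_code):
                argmin.append(code)
        out[combo_key] = PredictedMapping(
            combo_key[0], combo_key[1], tuple(argmin), best
        )
    return out


def evaluate(
    gold: list[GoldMapping],
    predictions: dict[tuple[str, str], PredictedMapping],
    shared: dict[tuple[str, str, str], object],
) -> EvalReport:
    """Tabulate relatedness and rebuild statistics over the gold rows.

    ``shared`` maps (topo, morph, icd10) to the shared-branch antichain of
    that row (or ``NOT_EVALUABLE``).  A row counts as related when it has at
    least one shared branch, as multi-branch when it has more than one, as
    rebuilt when its gold code is among the predicted codes of its
    combination, and as non-unique when that combination predicted more
    than one code.
    """
    report = EvalReport()
    for row in gold:
        key = (row.topo_code, row.morph_code, row.icd10_code)
        branches = shared.get(key, NOT_EVALUABLE)
        if branches == NOT_EVALUABLE:
            report.n_not_evaluable += 1
            continue
        for counts in (report.total, report.by_stratum[row.stratum]):
            counts.n_evaluable += 1
            if branches:
                counts.n_related += 1
                if len(branches) > 1:
                    counts.n_multibranch += 1
            pred = predictions.get((row.topo_code, row.morph_code))
            if pred is not None and row.icd10_code in pred.predicted:
                counts.n_rebuilt += 1
                if len(pred.predicted) > 1:
                    counts.n_nonunique += 1
    return report


def _rows(report: EvalReport):
    yield ("All", report.total)
    yield ("Hematopoietic tumors", report.by_stratum[Stratum.HEMATOPOIETIC])
    yield ("Solid tumors", report.by_stratum[Stratum.SOLID])


def write_eval_tsv(report: EvalReport, path: Path | str, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("stratum\tn_evaluable\tn_related\tn_multibranch\tn_rebuilt\tn_nonunique\n")
        for name, c in _rows(report):
            fh.write(
                f"{name}\t{c.n_evaluable}\t{c.n_related}\t{c.n_multibranch}"
                f"\t{c.n_rebuilt}\t{c.n_nonunique}\n"
            )


def write_eval_json(report: EvalReport, path: Path | str, header: str = "") -> None:
    payload = {
        "meta": header,
        "n_not_evaluable": report.n_not_evaluable,
        "strata": {
            name: {
                "n_evaluable": c.n_evaluable,
                "n_related": c.n_related,
                "n_multibranch": c.n_multibranch,
                "n_rebuilt": c.n_rebuilt,
                "n_nonunique": c.n_nonunique,
            }
            for name, c in _rows(report)
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
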