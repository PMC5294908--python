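"""Behavior-stratified morphology axis and "refined" concept index.

The source ontology has no morphology axis of its own: morphologies and
diagnoses live in one neoplasm hierarchy.  This module materializes the
missing axis from the ICD-O-3 morphology annotations carried by neoplasm
concepts.  Every distinct annotated code ``HHHH/B`` becomes one morphology
class, placed directly under the behavior class named by its fifth digit
(``/0`` benign, ``/1`` unknown whether benign or malignant, ``/2`` in situ,
``/3`` malignant primary, ``/6`` malignant metastatic, ``/9`` unknown whether
primary or metastatic).  The axis is deliberately flat below the behavior
level: the same histology with two behavior digits yields two incomparable
classes, and no histological hierarchy is asserted.

"Refined" concepts carry their morphology downward through the neoplasm
is_a hierarchy: a concept inherits every morphology annotation and every
primary-site filler of every is_a ancestor (including itself).  This
inheritance is what lets a concept such as a colon cavernous hemangioma be
related to both the cavernous-hemangioma and the hemangioma-NOS codes, and
is also what propagates an invasive code onto an in-situ concept — a source
inconsistency the audit stage is designed to surface, so it is preserved
here rather than filtered.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx

from .core import (
    MORPH_ROOT,
    DEFAULT_NAMESPACE,
    Axis,
    BehaviorClass,
    CycleError,
    DxLatticeError,
    MorphClass,
)

__all__ = [
    "MorphologyFormatError",
    "MorphologyAxis",
    "RefinedConceptIndex",
    "parse_morphology_code",
    "behavior_class_of",
    "build_morphology_axis",
    "compute_refined_index",
]

_CODE_RE = re.compile(r"^(\d{4})/(\d)$")

#: fixed behavior-digit -> class table (overridable only by an explicit map)
BEHAVIOR_DIGIT_TABLE: dict[int, BehaviorClass] = {
    0: BehaviorClass.BENIGN,
    1: BehaviorClass.UNKNOWN_BENIGN_MALIGNANT,
    2: BehaviorClass.IN_SITU,
    3: BehaviorClass.MALIGNANT_PRIMARY,
    6: BehaviorClass.MALIGNANT_METASTATIC,
    9: BehaviorClass.UNKNOWN_PRIMARY_METASTATIC,
}


class MorphologyFormatError(DxLatticeError, ValueError):
    pass


def parse_morphology_code(text: str) -> tuple[str, int]:
    """Split ``"HHHH/B"`` into (histology, behavior digit), keeping zeros."""
    m = _CODE_RE.match(text.strip())
    if not m:
        raise MorphologyFormatError(f"not an ICD-O-3 morphology code: {text!r}")
    return m.group(1), int(m.group(2))


def behavior_class_of(digit: int, table: dict[int, BehaviorClass] | None = None) -> BehaviorClass:
    table = table if table is not None else BEHAVIOR_DIGIT_TABLE
    try:
        return table[digit]
    except KeyError:
        raise MorphologyFormatError(f"invalid ICD-O-3 behavior digit: {digit}") from None


@dataclass
class MorphologyAxis:
    """Root + six behavior classes + one class per distinct annotated code."""

    specific: dict[str, MorphClass] = field(default_factory=dict)
    namespace: str = DEFAULT_NAMESPACE

    root_id: str = MORPH_ROOT

    def contains(self, morph_id: str) -> bool:
        if morph_id == self.root_id:
            return True
        if morph_id in BehaviorClass.__members__:
            return True
        return morph_id in self.specific

    def behavior_of(self, morph_id: str) -> BehaviorClass | None:
        """Behavior of a morphology id; None for the root."""
        if morph_id == self.root_id:
            return None
        if morph_id in BehaviorClass.__members__:
            return BehaviorClass[morph_id]
        return self.specific[morph_id].behavior

    def parent_of(self, morph_id: str) -> str | None:
        if morph_id == self.root_id:
            return None
        if morph_id in BehaviorClass.__members__:
            return self.root_id
        return self.specific[morph_id].behavior.value

    def all_ids(self) -> list[str]:
        return [self.root_id] + sorted(BehaviorClass.__members__) + sorted(self.specific)

    def candidate_morph_ids(self) -> list[str]:
        """Morphology ids entering candidate generation: behavior roots plus
        all specific classes (the root itself is not a candidate)."""
        return sorted(BehaviorClass.__members__) + sorted(self.specific)

    def up_set(self, morph_id: str) -> frozenset[str]:
        """All ids subsuming ``morph_id`` (including itself)."""
        out = {morph_id, self.root_id}
        b = self.behavior_of(morph_id)
        if b is not None:
            out.add(b.value)
        return frozenset(out)

    def __len__(self) -> int:
        return 7 + len(self.specific)


def build_morphology_axis(
    neo: "object",
    *,
    namespace: str = DEFAULT_NAMESPACE,
    digit_table: dict[int, BehaviorClass] | None = None,
) -> MorphologyAxis:
    """One morphology class per distinct annotated ICD-O-3 code.

    The six behavior classes are always present, even when no code of that
    behavior was ever annotated.  Parse failures are aggregated and reported
    with their concept context.
    """
    axis = MorphologyAxis(namespace=namespace)
    errors: list[str] = []
    for concept_id in sorted(neo.morph_annotations):
        for code in sorted(neo.morph_annotations[concept_id]):
            try:
                _, digit = parse_morphology_code(code)
                behavior = behavior_class_of(digit, digit_table)
            except MorphologyFormatError as exc:
                errors.append(f"{concept_id}: {exc}")
                continue
            if code not in axis.specific:
                iri = f"{namespace}M_{code.replace('/', '_')}"
                axis.specific[code] = MorphClass(code, behavior, iri)
    if errors:
        raise MorphologyFormatError(
            "morphology annotations failed to parse: " + "; ".join(errors)
        )
    return axis


@dataclass
class RefinedConceptIndex:
    """Per neoplasm concept, the is_a-inherited morphology and site sets."""

    inherited_morphs: dict[str, frozenset[str]] = field(default_factory=dict)
    inherited_sites: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.inherited_morphs


def compute_refined_index(neo: "object", axis: MorphologyAxis) -> RefinedConceptIndex:
    """Close morphology annotations and site fillers over is_a ancestors.

    For each neoplasm concept C, ``inherited_morphs(C)`` is the union of the
    annotated codes of C and of every is_a ancestor of C, and
    ``inherited_sites(C)`` likewise for primary-site fillers.
    """
    g = nx.DiGraph()
    ids = set(neo.concepts) if isinstance(neo.concepts, (set, dict)) else set(neo.concepts)
    g.add_nodes_from(ids)
    g.add_edges_from((c, p) for c, p in neo.is_a_edges if c in ids and p in ids)
    try:
        order = list(nx.topological_sort(g.reverse(copy=False)))
    except nx.NetworkXUnfeasible:
        raise CycleError(("is_a", "neoplasm axis"))
    morphs: dict[str, set[str]] = {}
    sites: dict[str, set[str]] = {}
    for n in order:
        m = set(neo.morph_annotations.get(n, ()))
        s = set(neo.site_fillers.get(n, ()))
        for _, parent in g.out_edges(n):
            m |= morphs[parent]
            s |= sites[parent]
        morphs[n] = m
        sites[n] = s
    return RefinedConceptIndex(
        inherited_morphs={k: frozenset(v) for k, v in morphs.items()},
        inherited_sites={k: frozenset(v) for k, v in sites.items()},
    )
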