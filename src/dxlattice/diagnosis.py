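"""Candidate generation and retention of diagnosis classes.

A candidate diagnosis is any pair (morphology class, reflexive-part
topography class): "something with this morphology arising in this site or
a part of it".  Candidates are streamed from the cross product of the
morphology axis (behavior classes included — retained classes may be as
coarse as "malignant, primary site: cecum reflexive part") and the
reflexive-part lattice.  A candidate is retained only when at least one
source concept satisfies it, i.e. when the concept's inherited morphology
set contains a morphology subsumed by the candidate's and its inherited
site set contains a site inside the candidate's topography.  Retention
keeps the full supporting-concept set; pruned candidates retain no storage.

The retention scan is indexed: for each concept the up-sets of its
inherited morphologies and sites are precomputed once, and satisfied
candidates are accumulated, so the morphology x topography product is never
walked per concept.  A naive double loop over all concept/candidate pairs
exists in :mod:`dxlattice.oracle` and serves as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .core import (
    DEFAULT_NAMESPACE,
    AnatomyIndex,
    DxClass,
    UnknownIdError,
    dx_subsumes,
    minimal_elements,
    transitive_reduction,
)
from .anatomy import RPLattice
from .morphology import MorphologyAxis, RefinedConceptIndex

__all__ = [
    "DxLattice",
    "generate_candidates",
    "concept_satisfies",
    "retain_diagnoses",
    "build_dx_lattice",
    "direct_dx_superclasses",
    "dx_iri",
]


def dx_iri(morph: str, base: str, namespace: str = DEFAULT_NAMESPACE) -> str:
    return f"{namespace}DX_{morph.replace('/', '_')}_{base.replace(':', '_')}"


@dataclass
class DxLattice:
    """Retained diagnosis classes with their Hasse diagram."""

    classes: dict[tuple[str, str], DxClass] = field(default_factory=dict)
    direct_edges: set[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=set)
    namespace: str = DEFAULT_NAMESPACE

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.classes

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self.classes)

    def __len__(self) -> int:
        return len(self.classes)


def generate_candidates(
    axis: MorphologyAxis, rp: RPLattice
) -> Iterator[tuple[str, str]]:
    """Stream (morphology id, topography base id) pairs in deterministic order.

    Yields exactly |behavior classes + specific morphologies| x |RP classes|
    pairs without materializing the product.
    """
    morph_ids = axis.candidate_morph_ids()
    bases = rp.bases()
    for m in morph_ids:
        for t in bases:
            yield (m, t)


def concept_satisfies(
    concept: str,
    cand: tuple[str, str],
    refined: RefinedConceptIndex,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
) -> bool:
    """Does this source concept fall under the candidate diagnosis?"""
    if concept not in refined:
        raise UnknownIdError(concept, "refined concept index")
    m, t = cand
    morph_ok = any(
        m in axis.up_set(mc) for mc in refined.inherited_morphs[concept]
    )
    if not morph_ok:
        return False
    return any(
        t in idx.up_set(s) for s in refined.inherited_sites[concept] if s in idx
    )


def retain_diagnoses(
    candidates: Iterable[tuple[str, str]],
    refined: RefinedConceptIndex,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
    rp: RPLattice,
    *,
    namespace: str = DEFAULT_NAMESPACE,
) -> list[DxClass]:
    """Retain candidates satisfied by at least one concept.

    Indexed scan: satisfied pairs are accumulated per concept from the
    product of its morphology up-sets and site up-sets (both small), then
    intersected with the candidate stream, so memory stays proportional to
    the satisfied set, not the full product.
    """
    support: dict[tuple[str, str], set[str]] = {}
    topos = set(rp.classes)
    for concept in sorted(refined.inherited_morphs):
        morph_up: set[str] = set()
        for mc in refined.inherited_morphs[concept]:
            morph_up |= axis.up_set(mc)
        morph_up.discard(axis.root_id)  # the root is not a candidate
        if not morph_up:
            continue
        site_up: set[str] = set()
        for s in refined.inherited_sites[concept]:
            if s in idx:
                site_up |= idx.up_set(s)
        site_up &= topos
        for m in morph_up:
            for t in site_up:
                support.setdefault((m, t), set()).add(concept)
    retained = []
    for m, t in candidates:
        concepts = support.get((m, t))
        if concepts:
            retained.append(
                DxClass(
                    morph=m,
                    rp_base=t,
                    iri=dx_iri(m, t, namespace),
                    supporting_concepts=frozenset(concepts),
                )
            )
    return retained


def build_dx_lattice(
    retained: Iterable[DxClass],
    axis: MorphologyAxis,
    idx: AnatomyIndex,
    *,
    namespace: str = DEFAULT_NAMESPACE,
) -> DxLattice:
    """Hasse diagram of the diagnosis order restricted to retained classes."""
    lattice = DxLattice(namespace=namespace)
    for d in retained:
        lattice.classes[d.key] = d

    def leq(k1: tuple[str, str], k2: tuple[str, str]) -> bool:
        return dx_subsumes(lattice.classes[k1], lattice.classes[k2], axis, idx)

    lattice.direct_edges = transitive_reduction(lattice.classes.keys(), leq)
    return lattice


def direct_dx_superclasses(
    concept: str,
    lattice: DxLattice,
    refined: RefinedConceptIndex,
    axis: MorphologyAxis,
    idx: AnatomyIndex,
) -> list[DxClass]:
    """Minimal retained diagnosis classes the concept satisfies (its direct
    types, an antichain)."""
    satisfied = [
        key
        for key in lattice.keys()
        if concept_satisfies(concept, key, refined, axis, idx)
    ]

    def leq(k1: tuple[str, str], k2: tuple[str, str]) -> bool:
        return dx_subsumes(lattice.classes[k1], lattice.classes[k2], axis, idx)

    return [lattice.classes[k] for k in minimal_elements(satisfied, leq)]
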