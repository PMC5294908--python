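"""Domain types and the structural order engine.

The derivative model rests on three partial orders:

* ``<=A`` — anatomical reachability: ``s <=A t`` holds when ``t`` can be
  reached from ``s`` by following any mixture of ``is_a`` and the two
  part-whole roles (``anatomic_structure_is_physical_part_of`` and
  ``anatomic_structure_has_location``), reflexively.  Both part roles are
  treated as transitive and freely composable with ``is_a``, which is what
  makes a chain such as Birbeck Granule -> Langerhans Cell -> Epidermis ->
  Skin count as "Birbeck Granule is in Skin".
* the morphology order — a flat two-level order: every specific ICD-O-3
  morphology sits directly under its behavior class (benign, in situ,
  malignant primary, ...), and all six behavior classes sit under a single
  morphology root.  Two specific morphologies are never comparable.
* the diagnosis order — the product order: D(m, t) is subsumed by
  D(m', t') iff m is subsumed by m' on the morphology axis and
  base(t) <=A base(t').

Subsumption is computed structurally with graph algorithms; the restricted
EL-style pattern (two existentials, no negation, no role hierarchies) makes
this sound and complete, so no general DL reasoner is involved.

All set-valued results are returned in lexicographic id order so that every
downstream artifact is deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Axis",
    "RoleKind",
    "BehaviorClass",
    "Concept",
    "SourceOntology",
    "AnatomyIndex",
    "RPClass",
    "MorphClass",
    "DxClass",
    "DxLatticeError",
    "UnknownIdError",
    "CycleError",
    "anat_reachable",
    "morph_subsumes",
    "dx_subsumes",
    "transitive_reduction",
    "minimal_elements",
]

MORPH_ROOT = "MORPH:ROOT"
#: prefix used for generated reflexive-part / diagnosis IRIs
DEFAULT_NAMESPACE = "http://example.org/dxlattice#"


class DxLatticeError(Exception):
    """Base class for all errors raised by this package."""


class UnknownIdError(DxLatticeError, KeyError):
    """An identifier was not found in the structure it was looked up in."""

    def __init__(self, identifier: str, where: str = "index"):
        super().__init__(f"unknown id {identifier!r} in {where}")
        self.identifier = identifier


class CycleError(DxLatticeError):
    """Antisymmetry failed: two distinct elements subsume each other."""

    def __init__(self, pair: tuple[str, str] | Sequence[str]):
        super().__init__(f"order is not antisymmetric; offending pair: {tuple(pair)}")
        self.pair = tuple(pair)


class Axis(str, enum.Enum):
    """Which axis of the source ontology a concept belongs to."""

    ANATOMY = "ANATOMY"
    NEOPLASM = "NEOPLASM"
    OTHER = "OTHER"


class RoleKind(str, enum.Enum):
    """The five roles the structural engine understands.

    ``PART_PHYSICAL`` and ``PART_LOCATION`` are the only roles used for
    reflexive-part construction; ``PRIMARY_SITE`` and ``HAS_FINDING`` are the
    only roles appearing in diagnosis definitions.
    """

    IS_A = "IS_A"
    PART_PHYSICAL = "PART_PHYSICAL"
    PART_LOCATION = "PART_LOCATION"
    PRIMARY_SITE = "PRIMARY_SITE"
    HAS_FINDING = "HAS_FINDING"


class BehaviorClass(str, enum.Enum):
    """The six tumoral behavior classes of ICD-O-3."""

    BENIGN = "BENIGN"
    IN_SITU = "IN_SITU"
    MALIGNANT_PRIMARY = "MALIGNANT_PRIMARY"
    MALIGNANT_METASTATIC = "MALIGNANT_METASTATIC"
    UNKNOWN_BENIGN_MALIGNANT = "UNKNOWN_BENIGN_MALIGNANT"
    UNKNOWN_PRIMARY_METASTATIC = "UNKNOWN_PRIMARY_METASTATIC"


@dataclass(frozen=True)
class Concept:
    id: str
    label: str = ""
    axis: Axis = Axis.OTHER


@dataclass
class SourceOntology:
    """An in-memory source ontology (NCIt-like).

    ``site_fillers`` maps a neoplasm concept to the anatomy concepts asserted
    as its primary anatomic sites; ``morph_annotations`` maps a concept to the
    ICD-O-3 morphology code strings (``HHHH/B``) it is annotated with.
    """

    concepts: dict[str, Concept] = field(default_factory=dict)
    is_a_edges: list[tuple[str, str]] = field(default_factory=list)
    part_edges: list[tuple[str, str, RoleKind]] = field(default_factory=list)
    site_fillers: dict[str, set[str]] = field(default_factory=dict)
    morph_annotations: dict[str, set[str]] = field(default_factory=dict)

    def concept_ids(self, axis: Axis | None = None) -> list[str]:
        if axis is None:
            return sorted(self.concepts)
        return sorted(c.id for c in self.concepts.values() if c.axis == axis)

    def label_of(self, concept_id: str) -> str:
        c = self.concepts.get(concept_id)
        return c.label if c is not None else concept_id


class AnatomyIndex:
    """Precomputed reflexive-transitive closure of the anatomy order ``<=A``.

    Built once from the anatomy subgraph (is_a plus both part roles); lookups
    are O(1) set membership afterwards.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]]):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            a, b = cycle[0][0], cycle[0][1]
            raise CycleError((a, b))
        self.graph = g
        # up-closure (ancestors under <=A) including self, per node
        self._up: dict[str, frozenset[str]] = {}
        for n in nx.topological_sort(g.reverse(copy=False)):
            up: set[str] = {n}
            for _, parent in g.out_edges(n):
                up |= self._up[parent]
            self._up[n] = frozenset(up)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._up

    def nodes(self) -> list[str]:
        return sorted(self._up)

    def up_set(self, concept_id: str) -> frozenset[str]:
        """All ``t`` with ``concept_id <=A t`` (including itself)."""
        try:
            return self._up[concept_id]
        except KeyError:
            raise UnknownIdError(concept_id, "anatomy index") from None

    def leq(self, s: str, t: str) -> bool:
        if t not in self._up:
            raise UnknownIdError(t, "anatomy index")
        return t in self.up_set(s)


@dataclass(frozen=True)
class RPClass:
    """A reflexive-part topography class: the site together with all its parts.

    ``RP(s)`` is subsumed by ``RP(t)`` exactly when ``s <=A t``.
    """

    base: str
    iri: str


@dataclass(frozen=True)
class MorphClass:
    """A morphology class keyed by its full ``HHHH/B`` ICD-O-3 code.

    The six behavior classes are themselves morphology classes (their
    ``icdo_code`` is the behavior name and ``behavior`` is themselves).
    """

    icdo_code: str
    behavior: BehaviorClass
    iri: str

    @property
    def is_behavior_root(self) -> bool:
        return self.icdo_code == self.behavior.value


@dataclass(frozen=True)
class DxClass:
    """A diagnosis class: a morphology paired with a reflexive-part site."""

    morph: str
    rp_base: str
    iri: str
    supporting_concepts: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, str]:
        return (self.morph, self.rp_base)


def anat_reachable(s: str, t: str, idx: AnatomyIndex) -> bool:
    """True iff ``t`` is reachable from ``s`` over is_a and part edges."""
    return idx.leq(s, t)


def morph_subsumes(a: str, b: str, axis) -> bool:
    """True iff morphology ``a`` is subsumed by morphology ``b``.

    Ids are either specific codes (``"8140/3"``), behavior names
    (``"MALIGNANT_PRIMARY"``) or the morphology root.  The axis is flat:
    a specific code is under exactly its behavior class; behavior classes
    are under the root; nothing else is comparable.
    """
    for x in (a, b):
        if not axis.contains(x):
            raise UnknownIdError(x, "morphology axis")
    if a == b or b == MORPH_ROOT:
        return True
    behavior = axis.behavior_of(a)
    if behavior is None:  # a is the root; only the root subsumes it
        return False
    if a == behavior.value:  # a is a behavior root
        return False
    return b == behavior.value


def dx_subsumes(d1: DxClass, d2: DxClass, axis, idx: AnatomyIndex) -> bool:
    """Product order on diagnosis classes."""
    return morph_subsumes(d1.morph, d2.morph, axis) and anat_reachable(
        d1.rp_base, d2.rp_base, idx
    )


def transitive_reduction(
    nodes: Iterable, leq: Callable[[object, object], bool]
) -> set[tuple]:
    """Hasse edges of a finite partial order.

    ``leq(x, y)`` must be a partial order on ``nodes`` (reflexive,
    transitive, antisymmetric); a :class:`CycleError` names one offending
    pair if antisymmetry fails.  Returns the unique minimal edge set whose
    reflexive-transitive closure equals the input order.
    """
    nodes = sorted(set(nodes))
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for x in nodes:
        for y in nodes:
            if x != y and leq(x, y):
                if g.has_edge(y, x):
                    raise CycleError((str(x), str(y)))
                g.add_edge(x, y)
    reduced = nx.transitive_reduction(g)
    return set(reduced.edges())


def minimal_elements(candidates: Iterable, leq: Callable[[object, object], bool]) -> list:
    """All candidates with no distinct candidate strictly below them.

    The result is an antichain, sorted for determinism.  Empty input yields
    an empty list.
    """
    cands = sorted(set(candidates))
    out = []
    for x in cands:
        if not any(y != x and leq(y, x) for y in cands):
            out.append(x)
    return out


def closure_of_edges(nodes: Iterable, edges: Iterable[tuple]) -> set[tuple]:
    """Reflexive-transitive closure of an edge set, as a set of pairs."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    clos = set()
    for n in g.nodes:
        clos.add((n, n))
        for d in nx.descendants(g, n):
            clos.add((n, d))
    return clos
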