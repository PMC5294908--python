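"""Reflexive-part (S-node) topography lattice.

A primary site is read as "the site itself or any of its parts": the tumor
of the digestive system may sit in any part of the digestive system.  Each
collected topography ``t`` therefore gets one generated class ``RP(t)``
standing for ``t U (part_of some t)``, and ``RP(s)`` is subsumed by
``RP(t)`` exactly when ``s <=A t`` in the anatomy order.  The classes are
materialized as primitive nodes carrying that defined order; the union
definition itself is only emitted at serialization time.

Topography collection applies ancestor completion by default: the asserted
site fillers of all neoplasm concepts plus every anatomy concept reachable
above them, so that coarse classes (a "Large Intestine reflexive part")
exist even when never directly asserted as a filler.  The completion can be
switched off to restrict the lattice to asserted fillers only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .core import DEFAULT_NAMESPACE, AnatomyIndex, RPClass
from .ingest import NeoplasmSubgraph

log = logging.getLogger(__name__)

__all__ = ["RPLattice", "collect_topographies", "build_rp_lattice"]


@dataclass
class RPLattice:
    """The generated reflexive-part hierarchy (one class per topography)."""

    classes: dict[str, RPClass] = field(default_factory=dict)  # base id -> class
    direct_edges: set[tuple[str, str]] = field(default_factory=set)  # Hasse, base ids
    namespace: str = DEFAULT_NAMESPACE

    def __contains__(self, base: str) -> bool:
        return base in self.classes

    def bases(self) -> list[str]:
        return sorted(self.classes)

    def __len__(self) -> int:
        return len(self.classes)


def collect_topographies(
    neo: NeoplasmSubgraph,
    anat: AnatomyIndex,
    *,
    ancestor_completion: bool = True,
) -> set[str]:
    """Topographies involved in at least one diagnosis definition.

    Union of all site fillers of all neoplasm concepts, optionally closed
    upward under ``<=A``.  Fillers missing from the anatomy index (already
    surfaced by validation) are excluded with a log entry.
    """
    topos: set[str] = set()
    for concept in sorted(neo.site_fillers):
        for filler in sorted(neo.site_fillers[concept]):
            if filler not in anat:
                log.warning(
                    "site filler %s of %s is not an anatomy concept; skipped",
                    filler, concept,
                )
                continue
            if ancestor_completion:
                topos |= anat.up_set(filler)
            else:
                topos.add(filler)
    return topos


def build_rp_lattice(
    topos: set[str], anat: AnatomyIndex, *, namespace: str = DEFAULT_NAMESPACE
) -> RPLattice:
    """One RP class per topography; Hasse edges of ``<=A`` restricted to them.

    IRIs are deterministic: ``<ns>RP_<anatomyId>``.
    """
    lattice = RPLattice(namespace=namespace)
    for base in sorted(topos):
        safe = base.replace(":", "_")
        lattice.classes[base] = RPClass(base=base, iri=f"{namespace}RP_{safe}")
    # closure restricted to the collected topographies, then Hasse reduction
    g = nx.DiGraph()
    g.add_nodes_from(topos)
    for base in topos:
        for anc in anat.up_set(base):
            if anc != base and anc in topos:
                g.add_edge(base, anc)
    reduced = nx.transitive_reduction(g)
    lattice.direct_edges = set(reduced.edges())
    return lattice
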