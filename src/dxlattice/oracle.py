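"""Naive rule-saturation oracle for the structural engine.

Everything here recomputes the model's relations from the raw source
ontology by fixpoint iteration and exhaustive double loops, sharing no code
with the indexed engine: reachability is saturated with an explicit
pair-set loop instead of a precomputed closure, inheritance is saturated
edge by edge instead of walked in topological order, retention enumerates
every concept x candidate pair, and the behavior-digit table is restated
locally.  The point is genuine independence: equivalence tests between the
engine and this oracle are meaningful only because neither can inherit the
other's bugs.

A size guard refuses models with more than 5000 candidate pairs; the
oracle is quadratic-to-cubic and intended for fixtures only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import Axis, RoleKind, SourceOntology

__all__ = ["OracleModel", "brute_force_oracle", "OracleSizeError"]

_ORACLE_DIGITS = {
    "0": "BENIGN",
    "1": "UNKNOWN_BENIGN_MALIGNANT",
    "2": "IN_SITU",
    "3": "MALIGNANT_PRIMARY",
    "6": "MALIGNANT_METASTATIC",
    "9": "UNKNOWN_PRIMARY_METASTATIC",
}
_ORACLE_ROOT = "MORPH:ROOT"
PAIR_GUARD = 5000


class OracleSizeError(Exception):
    pass


@dataclass
class OracleModel:
    """Fully materialized relations of the derivative model."""

    anat_pairs: set[tuple[str, str]] = field(default_factory=set)
    morph_ids: set[str] = field(default_factory=set)
    morph_pairs: set[tuple[str, str]] = field(default_factory=set)
    topographies: set[str] = field(default_factory=set)
    inherited_morphs: dict[str, set[str]] = field(default_factory=dict)
    inherited_sites: dict[str, set[str]] = field(default_factory=dict)
    satisfaction: set[tuple[str, str, str]] = field(default_factory=set)  # (C, m, t)
    retained: set[tuple[str, str]] = field(default_factory=set)
    dx_pairs: set[tuple[tuple[str, str], tuple[str, str]]] = field(default_factory=set)

    def anat_leq(self, s: str, t: str) -> bool:
        return (s, t) in self.anat_pairs

    def morph_leq(self, a: str, b: str) -> bool:
        return (a, b) in self.morph_pairs

    def dx_leq(self, k1: tuple[str, str], k2: tuple[str, str]) -> bool:
        return (k1, k2) in self.dx_pairs

    def direct_types(self, concept: str) -> list[tuple[str, str]]:
        """Minimal retained classes the concept satisfies (double loop)."""
        satisfied = sorted(
            k for k in self.retained if (concept, k[0], k[1]) in self.satisfaction
        )
        out = []
        for k in satisfied:
            if not any(j != k and self.dx_leq(j, k) for j in satisfied):
                out.append(k)
        return out


def _saturate_pairs(nodes: set[str], edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    pairs = {(n, n) for n in nodes} | set(edges)
    changed = True
    while changed:
        changed = False
        for (a, b) in list(pairs):
            for (c, d) in list(pairs):
                if b == c and (a, d) not in pairs:
                    pairs.add((a, d))
                    changed = True
    return pairs


def brute_force_oracle(
    onto: SourceOntology, *, ancestor_completion: bool = True
) -> OracleModel:
    """Compute every model relation by saturation from the raw ontology."""
    m = OracleModel()

    anatomy = {c.id for c in onto.concepts.values() if c.axis is Axis.ANATOMY}
    neoplasm = {c.id for c in onto.concepts.values() if c.axis is Axis.NEOPLASM}

    anat_edges = {
        (c, p) for c, p in onto.is_a_edges if c in anatomy and p in anatomy
    } | {
        (c, p)
        for c, p, r in onto.part_edges
        if c in anatomy and p in anatomy
        and r in (RoleKind.PART_PHYSICAL, RoleKind.PART_LOCATION)
    }
    m.anat_pairs = _saturate_pairs(anatomy, anat_edges)

    # morphology axis: ids + flat two-level order
    codes = set()
    for cid in neoplasm:
        codes |= set(onto.morph_annotations.get(cid, ()))
    m.morph_ids = {_ORACLE_ROOT} | set(_ORACLE_DIGITS.values()) | codes
    for x in m.morph_ids:
        m.morph_pairs.add((x, x))
        m.morph_pairs.add((x, _ORACLE_ROOT))
    for code in codes:
        behavior = _ORACLE_DIGITS[code.split("/")[1]]
        m.morph_pairs.add((code, behavior))

    # inherited annotations: saturate over is_a edges until fixpoint
    m.inherited_morphs = {c: set(onto.morph_annotations.get(c, ())) for c in neoplasm}
    m.inherited_sites = {c: set(onto.site_fillers.get(c, ())) & anatomy for c in neoplasm}
    neo_is_a = [(c, p) for c, p in onto.is_a_edges if c in neoplasm and p in neoplasm]
    changed = True
    while changed:
        changed = False
        for child, parent in neo_is_a:
            for store in (m.inherited_morphs, m.inherited_sites):
                before = len(store[child])
                store[child] |= store[parent]
                if len(store[child]) != before:
                    changed = True

    # topographies: asserted fillers, optionally closed upward
    fillers = {f for c in neoplasm for f in onto.site_fillers.get(c, ()) if f in anatomy}
    if ancestor_completion:
        m.topographies = {t for f in fillers for (s, t) in m.anat_pairs if s == f}
    else:
        m.topographies = set(fillers)

    candidate_morphs = sorted(set(_ORACLE_DIGITS.values()) | codes)
    n_pairs = len(candidate_morphs) * len(m.topographies)
    if n_pairs > PAIR_GUARD:
        raise OracleSizeError(f"{n_pairs} candidate pairs exceed the oracle guard")

    for concept in sorted(neoplasm):
        for cm in candidate_morphs:
            if not any(m.morph_leq(mc, cm) for mc in m.inherited_morphs[concept]):
                continue
            for t in sorted(m.topographies):
                if any(m.anat_leq(s, t) for s in m.inherited_sites[concept]):
                    m.satisfaction.add((concept, cm, t))
                    m.retained.add((cm, t))

    for k1 in sorted(m.retained):
        for k2 in sorted(m.retained):
            if m.morph_leq(k1[0], k2[0]) and m.anat_leq(k1[1], k2[1]):
                m.dx_pairs.add((k1, k2))
    return m
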