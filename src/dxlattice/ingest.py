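"""Reading the source ontology and projecting the builder subgraphs.

Two dialects are supported.

``NATIVE_TSV`` is the canonical tabular format: a directory holding four
UTF-8 tab-separated files with header rows (``#`` starts a comment line):

* ``concepts.tsv`` — ``id  label  axis`` with axis in ANATOMY/NEOPLASM/OTHER
* ``is_a.tsv`` — ``child  parent``
* ``part_edges.tsv`` — ``child  parent  role`` with role PART_PHYSICAL or
  PART_LOCATION
* ``role_assertions.tsv`` — ``concept  role  filler``; role PRIMARY_SITE
  (filler is an anatomy concept id) or MORPHOLOGY (filler is an ICD-O-3
  ``HHHH/B`` code string)

``TURTLE_OWL_SUBSET`` reads a restricted OWL/Turtle serialization: class
declarations, ``rdfs:subClassOf`` between named classes (is_a),
``rdfs:subClassOf`` of an ``owl:Restriction`` with ``owl:someValuesFrom``
on one of the four object roles, ``rdfs:label``, and a designated
annotation property carrying ICD-O-3 morphology codes.  Axis membership in
Turtle is derived by a root-descendant test against configured anatomy and
neoplasm root ids.  Anything else is counted and logged, never silently
dropped without a count.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .core import (
    AnatomyIndex,
    Axis,
    Concept,
    DxLatticeError,
    RoleKind,
    SourceOntology,
)

log = logging.getLogger(__name__)

__all__ = [
    "OntologyDialect",
    "IngestError",
    "ValidationReport",
    "AnatomySubgraph",
    "NeoplasmSubgraph",
    "load_source_ontology",
    "write_native_tsv",
    "write_source_turtle",
    "extract_anatomy_graph",
    "extract_neoplasm_graph",
    "validate_graphs",
]

TSV_FILES = ("concepts.tsv", "is_a.tsv", "part_edges.tsv", "role_assertions.tsv")

SRC_NS = "http://example.org/dxlattice/source/"
MORPH_ANNOTATION_IRI = SRC_NS + "icdo3_morphology"
ROLE_IRIS = {
    RoleKind.PART_PHYSICAL: SRC_NS + "anatomic_structure_is_physical_part_of",
    RoleKind.PART_LOCATION: SRC_NS + "anatomic_structure_has_location",
    RoleKind.PRIMARY_SITE: SRC_NS + "disease_has_primary_anatomic_site",
    RoleKind.HAS_FINDING: SRC_NS + "disease_has_finding",
}
IRI_ROLES = {v: k for k, v in ROLE_IRIS.items()}


class OntologyDialect(str):
    pass


NATIVE_TSV = "NATIVE_TSV"
TURTLE_OWL_SUBSET = "TURTLE_OWL_SUBSET"


class IngestError(DxLatticeError):
    pass


@dataclass
class ValidationReport:
    """Outcome of structural validation; empty iff the ontology is clean."""

    cycles: list[list[str]] = field(default_factory=list)
    dangling: list[tuple[tuple, str]] = field(default_factory=list)
    off_axis_sites: list[tuple[str, str]] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.cycles or self.dangling or self.off_axis_sites)


@dataclass
class AnatomySubgraph:
    concepts: set[str]
    is_a_edges: list[tuple[str, str]]
    part_edges: list[tuple[str, str, RoleKind]]


@dataclass
class NeoplasmSubgraph:
    concepts: set[str]
    is_a_edges: list[tuple[str, str]]
    site_fillers: dict[str, set[str]]
    morph_annotations: dict[str, set[str]]


def _curie_to_iri(curie: str) -> str:
    return SRC_NS + curie.replace(":", "/", 1)


def _iri_to_curie(iri: str) -> str:
    local = iri[len(SRC_NS):]
    return local.replace("/", ":", 1)


def _read_tsv(path: Path, expected_header: tuple[str, ...]) -> list[list[str]]:
    if not path.exists():
        raise IngestError(f"missing NATIVE_TSV file: {path}")
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(
            (line for line in fh if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        header = next(reader, None)
        if header is None:
            return []
        if tuple(h.strip() for h in header) != expected_header:
            raise IngestError(
                f"{path.name}: expected header {expected_header}, got {tuple(header)}"
            )
        for i, row in enumerate(reader, start=2):
            if len(row) != len(expected_header):
                raise IngestError(f"{path.name}:{i}: expected {len(expected_header)} fields")
            rows.append([f.strip() for f in row])
    return rows


def _load_native_tsv(root: Path) -> SourceOntology:
    onto = SourceOntology()
    for cid, label, axis in _read_tsv(root / "concepts.tsv", ("id", "label", "axis")):
        if cid in onto.concepts:
            raise IngestError(f"duplicate concept id {cid!r}")
        onto.concepts[cid] = Concept(cid, label, Axis(axis))
    for child, parent in _read_tsv(root / "is_a.tsv", ("child", "parent")):
        onto.is_a_edges.append((child, parent))
    for child, parent, role in _read_tsv(root / "part_edges.tsv", ("child", "parent", "role")):
        kind = RoleKind(role)
        if kind not in (RoleKind.PART_PHYSICAL, RoleKind.PART_LOCATION):
            raise IngestError(f"part_edges.tsv: role must be a part role, got {role}")
        onto.part_edges.append((child, parent, kind))
    for concept, role, filler in _read_tsv(
        root / "role_assertions.tsv", ("concept", "role", "filler")
    ):
        if role == "PRIMARY_SITE":
            onto.site_fillers.setdefault(concept, set()).add(filler)
        elif role == "MORPHOLOGY":
            onto.morph_annotations.setdefault(concept, set()).add(filler)
        else:
            raise IngestError(f"role_assertions.tsv: unknown role {role!r}")
    return onto


def write_native_tsv(onto: SourceOntology, root: Path | str) -> None:
    """Serialize to the canonical four-file layout (lossless, sorted)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "concepts.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\taxis\n")
        for cid in sorted(onto.concepts):
            c = onto.concepts[cid]
            fh.write(f"{c.id}\t{c.label}\t{c.axis.value}\n")
    with open(root / "is_a.tsv", "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(set(onto.is_a_edges)):
            fh.write(f"{child}\t{parent}\n")
    with open(root / "part_edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("child\tparent\trole\n")
        for child, parent, role in sorted(set(onto.part_edges)):
            fh.write(f"{child}\t{parent}\t{role.value}\n")
    with open(root / "role_assertions.tsv", "w", encoding="utf-8") as fh:
        fh.write("concept\trole\tfiller\n")
        rows = []
        for concept in onto.site_fillers:
            rows += [(concept, "PRIMARY_SITE", f) for f in onto.site_fillers[concept]]
        for concept in onto.morph_annotations:
            rows += [(concept, "MORPHOLOGY", f) for f in onto.morph_annotations[concept]]
        for concept, role, filler in sorted(rows):
            fh.write(f"{concept}\t{role}\t{filler}\n")


def write_source_turtle(onto: SourceOntology, path: Path | str,
                        anatomy_root: str | None = None,
                        neoplasm_root: str | None = None) -> None:
    """Serialize the source ontology in the recognized OWL/Turtle subset.

    Axis information is not written explicitly; it is recovered on load by
    the root-descendant test, so callers pass the same roots on both sides.
    """
    lines = [
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        f"@prefix src: <{SRC_NS}> .",
        "",
    ]

    def ref(curie: str) -> str:
        return f"<{_curie_to_iri(curie)}>"

    for cid in sorted(onto.concepts):
        c = onto.concepts[cid]
        lines.append(f"{ref(cid)} a owl:Class ;")
        label = c.label.replace("\\", "\\\\").replace('"', '\\"')
        lines.append(f'    rdfs:label "{label}" .')
    for child, parent in sorted(set(onto.is_a_edges)):
        lines.append(f"{ref(child)} rdfs:subClassOf {ref(parent)} .")
    restriction_rows = [
        (child, ROLE_IRIS[role], parent)
        for child, parent, role in set(onto.part_edges)
    ] + [
        (concept, ROLE_IRIS[RoleKind.PRIMARY_SITE], filler)
        for concept, fillers in onto.site_fillers.items()
        for filler in fillers
    ]
    for subj, prop, obj in sorted(restriction_rows):
        lines.append(
            f"{ref(subj)} rdfs:subClassOf [ a owl:Restriction ; "
            f"owl:onProperty <{prop}> ; owl:someValuesFrom {ref(obj)} ] ."
        )
    annot_rows = sorted(
        (c, code) for c, codes in onto.morph_annotations.items() for code in codes
    )
    for concept, code in annot_rows:
        lines.append(f'{ref(concept)} <{MORPH_ANNOTATION_IRI}> "{code}" .')
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _load_turtle(path: Path, anatomy_root: str | None, neoplasm_root: str | None) -> SourceOntology:
    import rdflib
    from rdflib.namespace import OWL, RDF, RDFS

    g = rdflib.Graph()
    try:
        g.parse(str(path), format="turtle")
    except Exception as exc:  # rdflib raises several parser error types
        raise IngestError(f"Turtle parse error in {path}: {exc}") from exc

    onto = SourceOntology()
    labels: dict[str, str] = {}
    recognized = 0
    unrecognized = 0

    def curie(node) -> str | None:
        s = str(node)
        return _iri_to_curie(s) if s.startswith(SRC_NS) else None

    for s in g.subjects(RDF.type, OWL.Class):
        cid = curie(s)
        if cid is not None:
            onto.concepts[cid] = Concept(cid, "", Axis.OTHER)
            recognized += 1
    for s, o in g.subject_objects(RDFS.label):
        cid = curie(s)
        if cid is not None:
            labels[cid] = str(o)
            recognized += 1
    for s, o in g.subject_objects(RDFS.subClassOf):
        cid = curie(s)
        if cid is None:
            unrecognized += 1
            continue
        target = curie(o)
        if target is not None:
            onto.is_a_edges.append((cid, target))
            recognized += 1
            continue
        # restriction b-node
        prop = g.value(o, OWL.onProperty)
        filler = g.value(o, OWL.someValuesFrom)
        role = IRI_ROLES.get(str(prop)) if prop is not None else None
        filler_id = curie(filler) if filler is not None else None
        if role is None or filler_id is None:
            unrecognized += 1
            continue
        if role in (RoleKind.PART_PHYSICAL, RoleKind.PART_LOCATION):
            onto.part_edges.append((cid, filler_id, role))
        elif role is RoleKind.PRIMARY_SITE:
            onto.site_fillers.setdefault(cid, set()).add(filler_id)
        else:  # HAS_FINDING restrictions in the source are accepted, unused
            unrecognized += 1
            continue
        recognized += 1
    for s, o in g.subject_objects(rdflib.URIRef(MORPH_ANNOTATION_IRI)):
        cid = curie(s)
        if cid is not None:
            onto.morph_annotations.setdefault(cid, set()).add(str(o))
            recognized += 1

    for cid, label in labels.items():
        if cid in onto.concepts:
            onto.concepts[cid] = Concept(cid, label, Axis.OTHER)

    # axis tagging by root-descendant test over is_a + part edges
    up = nx.DiGraph()
    up.add_nodes_from(onto.concepts)
    up.add_edges_from((c, p) for c, p in onto.is_a_edges)
    up.add_edges_from((c, p) for c, p, _ in onto.part_edges)
    for root, axis in ((anatomy_root, Axis.ANATOMY), (neoplasm_root, Axis.NEOPLASM)):
        if root is None or root not in onto.concepts:
            continue
        members = {root} | nx.ancestors(up, root)
        for cid in members:
            old = onto.concepts[cid]
            onto.concepts[cid] = Concept(cid, old.label, axis)
    if unrecognized:
        log.warning("Turtle load: %d unrecognized axioms skipped (%d recognized)",
                    unrecognized, recognized)
    return onto


def load_source_ontology(
    path: Path | str,
    dialect: str = NATIVE_TSV,
    *,
    anatomy_root: str | None = None,
    neoplasm_root: str | None = None,
) -> SourceOntology:
    """Load a source ontology under the declared dialect."""
    path = Path(path)
    if dialect == NATIVE_TSV:
        if not path.is_dir():
            raise IngestError(f"NATIVE_TSV expects a directory, got {path}")
        return _load_native_tsv(path)
    if dialect == TURTLE_OWL_SUBSET:
        if not path.is_file():
            raise IngestError(f"Turtle dialect expects a file, got {path}")
        return _load_turtle(path, anatomy_root, neoplasm_root)
    raise IngestError(f"unknown ontology dialect: {dialect!r}")


def _axis_cycles(onto: SourceOntology, axis: Axis) -> list[list[str]]:
    ids = {c.id for c in onto.concepts.values() if c.axis == axis}
    g = nx.DiGraph()
    g.add_nodes_from(ids)
    g.add_edges_from((c, p) for c, p in onto.is_a_edges if c in ids and p in ids)
    if axis is Axis.ANATOMY:
        g.add_edges_from((c, p) for c, p, _ in onto.part_edges if c in ids and p in ids)
    cycles = []
    try:
        cyc = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return cycles
    nodes = [e[0] for e in cyc] + [cyc[0][0]]
    cycles.append(nodes)
    return cycles


def validate_graphs(onto: SourceOntology) -> ValidationReport:
    """Detect is_a cycles per axis, dangling edges, off-axis site fillers."""
    report = ValidationReport()
    for axis in (Axis.ANATOMY, Axis.NEOPLASM, Axis.OTHER):
        report.cycles.extend(_axis_cycles(onto, axis))
    known = set(onto.concepts)
    for edge in onto.is_a_edges:
        for end in edge:
            if end not in known:
                report.dangling.append((edge, end))
    for child, parent, role in onto.part_edges:
        for end in (child, parent):
            if end not in known:
                report.dangling.append(((child, parent, role.value), end))
    for concept, fillers in sorted(onto.site_fillers.items()):
        if concept not in known:
            report.dangling.append(((concept, "PRIMARY_SITE"), concept))
            continue
        for filler in sorted(fillers):
            if filler not in known:
                report.dangling.append(((concept, "PRIMARY_SITE", filler), filler))
            elif onto.concepts[filler].axis is not Axis.ANATOMY:
                report.off_axis_sites.append((concept, filler))
    return report


def collapse_cycles(onto: SourceOntology) -> SourceOntology:
    """Collapse each strongly connected component into its lexicographically
    smallest member.

    Cycles are fatal by default (a source-data error should not silently
    alter semantics); this opt-in repair rewrites every edge, site filler
    and annotation onto the representative and drops self-edges.
    """
    g = nx.DiGraph()
    g.add_nodes_from(onto.concepts)
    g.add_edges_from(onto.is_a_edges)
    g.add_edges_from((c, p) for c, p, _ in onto.part_edges)
    rep: dict[str, str] = {}
    for scc in nx.strongly_connected_components(g):
        r = min(scc)
        for n in scc:
            rep[n] = r
    out = SourceOntology()
    for cid, c in onto.concepts.items():
        r = rep.get(cid, cid)
        if r == cid:
            out.concepts[cid] = c
    out.is_a_edges = sorted(
        {(rep[c], rep[p]) for c, p in onto.is_a_edges if rep[c] != rep[p]}
    )
    out.part_edges = sorted(
        {(rep[c], rep[p], r) for c, p, r in onto.part_edges if rep[c] != rep[p]},
        key=lambda e: (e[0], e[1], e[2].value),
    )
    for c, fillers in onto.site_fillers.items():
        out.site_fillers.setdefault(rep[c], set()).update(rep[f] for f in fillers if f in rep)
    for c, codes in onto.morph_annotations.items():
        out.morph_annotations.setdefault(rep[c], set()).update(codes)
    return out


def extract_anatomy_graph(onto: SourceOntology) -> tuple[AnatomySubgraph, AnatomyIndex]:
    """Project the anatomy axis and precompute its reachability closure."""
    ids = {c.id for c in onto.concepts.values() if c.axis is Axis.ANATOMY}
    is_a = [(c, p) for c, p in onto.is_a_edges if c in ids and p in ids]
    parts = [(c, p, r) for c, p, r in onto.part_edges if c in ids and p in ids]
    sub = AnatomySubgraph(ids, is_a, parts)
    idx = AnatomyIndex(ids, [(c, p) for c, p in is_a] + [(c, p) for c, p, _ in parts])
    return sub, idx


def extract_neoplasm_graph(onto: SourceOntology) -> NeoplasmSubgraph:
    """Project the neoplasm axis with its site fillers and annotations."""
    ids = {c.id for c in onto.concepts.values() if c.axis is Axis.NEOPLASM}
    is_a = [(c, p) for c, p in onto.is_a_edges if c in ids and p in ids]
    sites = {c: set(f) for c, f in onto.site_fillers.items() if c in ids}
    morphs = {c: set(m) for c, m in onto.morph_annotations.items() if c in ids}
    return NeoplasmSubgraph(ids, is_a, sites, morphs)
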