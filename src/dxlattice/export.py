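"""Serialization of the derivative model and binding tables.

The model is written as a SKOS/OWL hybrid in Turtle: every generated class
is a subclass of ``skos:Concept`` so that terminology codes can instantiate
it as individuals, reflexive-part classes carry their defining union
(``X or (part_of some X)``), diagnosis classes carry their defining
intersection of the two existential restrictions, and the Hasse edges of
each lattice are emitted as ``rdfs:subClassOf``.  Output is written with a
fixed prefix block, sorted statements and no timestamps, so identical
models serialize to identical bytes.
"""

from __future__ import annotations

from pathlib import Path

from .core import BehaviorClass, MORPH_ROOT
from .ingest import SRC_NS, ROLE_IRIS, _curie_to_iri
from .terminology import BindingResult, System

__all__ = ["serialize_derivative_model", "write_bindings_tsv"]

PREFIX_BLOCK = """@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix skos: <http://www.w3.org/2004/02/skos/core#> .
@prefix src: <{src}> .
@prefix dxl: <{ns}> .

dxl:ontology a owl:Ontology .
dxl:part_of a owl:ObjectProperty .
dxl:disease_has_finding a owl:ObjectProperty .
dxl:disease_has_primary_anatomic_site a owl:ObjectProperty .
"""


def _src(curie: str) -> str:
    return f"<{_curie_to_iri(curie)}>"


def _rp_name(base: str) -> str:
    return "dxl:RP_" + base.replace(":", "_")


def _m_name(morph: str) -> str:
    if morph == MORPH_ROOT:
        return "dxl:MORPHOLOGY"
    if morph in BehaviorClass.__members__:
        return "dxl:B_" + morph
    return "dxl:M_" + morph.replace("/", "_")


def _dx_name(key: tuple[str, str]) -> str:
    return "dxl:DX_" + key[0].replace("/", "_") + "_" + key[1].replace(":", "_")


def serialize_derivative_model(model, path: Path | str, bindings=None) -> None:
    """Write the model (and optional code individuals) as Turtle."""
    ns = model.rp.namespace
    lines = [PREFIX_BLOCK.format(src=SRC_NS, ns=ns)]

    # morphology axis
    lines.append("dxl:MORPHOLOGY a owl:Class ; rdfs:subClassOf skos:Concept .")
    for behavior in sorted(BehaviorClass.__members__):
        lines.append(
            f"dxl:B_{behavior} a owl:Class ; "
            "rdfs:subClassOf skos:Concept , dxl:MORPHOLOGY ."
        )
    for code in sorted(model.axis.specific):
        mc = model.axis.specific[code]
        lines.append(
            f'{_m_name(code)} a owl:Class ; rdfs:label "{code}" ; '
            f"rdfs:subClassOf skos:Concept , dxl:B_{mc.behavior.value} ."
        )

    # reflexive-part lattice: defining unions plus Hasse edges
    for base in model.rp.bases():
        lines.append(
            f"{_rp_name(base)} a owl:Class ; rdfs:subClassOf skos:Concept ; "
            "owl:equivalentClass [ a owl:Class ; owl:unionOf ( "
            f"{_src(base)} [ a owl:Restriction ; owl:onProperty dxl:part_of ; "
            f"owl:someValuesFrom {_src(base)} ] ) ] ."
        )
    for sub, sup in sorted(model.rp.direct_edges):
        lines.append(f"{_rp_name(sub)} rdfs:subClassOf {_rp_name(sup)} .")

    # diagnosis lattice: defining intersections plus Hasse edges
    for key in model.dx.keys():
        lines.append(
            f"{_dx_name(key)} a owl:Class ; rdfs:subClassOf skos:Concept ; "
            "owl:equivalentClass [ a owl:Class ; owl:intersectionOf ( "
            f"[ a owl:Restriction ; owl:onProperty dxl:disease_has_finding ; "
            f"owl:someValuesFrom {_m_name(key[0])} ] "
            f"[ a owl:Restriction ; owl:onProperty dxl:disease_has_primary_anatomic_site ; "
            f"owl:someValuesFrom {_rp_name(key[1])} ] ) ] ."
        )
    for sub, sup in sorted(model.dx.direct_edges):
        lines.append(f"{_dx_name(sub)} rdfs:subClassOf {_dx_name(sup)} .")

    # terminology codes as individuals typed by their direct classes
    if bindings is not None:
        for b in sorted(bindings.all(), key=lambda b: (b.system.value, b.code)):
            if not b.bound:
                continue
            safe = b.code.replace(".", "_").replace("/", "_")
            name = f"dxl:code_{b.system.value}_{safe}"
            if b.system is System.ICDO3_T:
                types = [_rp_name(base) for base in b.direct_classes]
            elif b.system is System.ICDO3_M:
                types = [_m_name(m) for m in b.direct_classes]
            else:
                types = [_dx_name(k) for k in b.direct_classes]
            lines.append(
                f'{name} a {" , ".join(sorted(types))} ; rdfs:label "{b.code}" .'
            )

    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_bindings_tsv(bindings, path: Path | str, header: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("code\tsystem\tstatus\tn_classes\tclasses\treason\n")
        for b in sorted(bindings.all(), key=lambda b: (b.system.value, b.code)):
            classes = ";".join(str(c) for c in b.direct_classes)
            fh.write(
                f"{b.code}\t{b.system.value}\t{b.status.value}"
                f"\t{len(b.direct_classes)}\t{classes}\t{b.reason}\n"
            )
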