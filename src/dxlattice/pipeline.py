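"""Pipeline configuration and stage orchestration.

``build_model`` assembles the derivative model from a source ontology:
anatomy extraction, morphology axis, refined-concept index, topography
collection, reflexive-part lattice, candidate streaming and retention, and
the diagnosis Hasse lattice.  ``bind_terminologies`` instantiates the model
with code lists through the CUI crosswalk.  ``run_pipeline`` chains
build -> bind -> audit -> evaluate and writes every artifact; the
evaluation stage is skipped with a notice when no gold file is configured.

The configuration is a flat key-value document validated before any stage
runs; unknown keys are rejected and every default is logged at startup so
a run is fully reproducible from its log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from . import __version__
from .core import DEFAULT_NAMESPACE, AnatomyIndex, SourceOntology
from .anatomy import RPLattice, build_rp_lattice, collect_topographies
from .audit import (
    AuditReport,
    behavior_conflicts,
    inconsistency_hypotheses,
    multi_instantiation_report,
    write_audit_json,
    write_audit_tsv,
)
from .diagnosis import DxLattice, build_dx_lattice, generate_candidates, retain_diagnoses
from .evaluation import (
    EvalReport,
    evaluate,
    read_seer_conversion,
    rebuild_mappings,
    shared_branches,
    write_eval_json,
    write_eval_tsv,
)
from .ingest import (
    NATIVE_TSV,
    AnatomySubgraph,
    NeoplasmSubgraph,
    extract_anatomy_graph,
    extract_neoplasm_graph,
    load_source_ontology,
    validate_graphs,
)
from .morphology import (
    MorphologyAxis,
    RefinedConceptIndex,
    build_morphology_axis,
    compute_refined_index,
)
from .terminology import (
    BindingResult,
    CuiCrosswalk,
    System,
    bind_icd10,
    bind_morphology,
    bind_topography,
    read_cui_map,
    read_terminology,
    satisfied_dx_of_combination,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "DerivativeModel", "Bindings", "build_model",
           "bind_terminologies", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    ontology_path: str = ""
    ontology_dialect: str = NATIVE_TSV
    anatomy_root: str | None = None
    neoplasm_root: str | None = None
    icd10_path: str | None = None
    icdo3_topo_path: str | None = None
    icdo3_morph_path: str | None = None
    crosswalk_path: str | None = None
    crosswalk_dialect: str = "TSV"
    seer_path: str | None = None
    namespace: str = DEFAULT_NAMESPACE
    ancestor_completion: bool = True
    collapse_cycles: bool = False
    seed: int = 0
    output_dir: str = "dxlattice-out"

    def config_hash(self) -> str:
        # output location does not affect the science; keep it out of the hash
        payload = json.dumps(
            self.model_dump(exclude={"output_dir"}), sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def artifact_header(self) -> str:
        return f"dxlattice {__version__} config={self.config_hash()} seed={self.seed}"


@dataclass
class DerivativeModel:
    """Everything the builders produce, ready for binding and auditing."""

    onto: SourceOntology
    anat: AnatomySubgraph
    idx: AnatomyIndex
    neo: NeoplasmSubgraph
    axis: MorphologyAxis
    refined: RefinedConceptIndex
    rp: RPLattice
    dx: DxLattice
    n_candidates: int = 0


@dataclass
class Bindings:
    icd10: dict[str, BindingResult] = field(default_factory=dict)
    topo: dict[str, BindingResult] = field(default_factory=dict)
    morph: dict[str, BindingResult] = field(default_factory=dict)

    def all(self) -> list[BindingResult]:
        out = list(self.topo.values()) + list(self.morph.values())
        return out + list(self.icd10.values())


def build_model(
    onto: SourceOntology,
    *,
    namespace: str = DEFAULT_NAMESPACE,
    ancestor_completion: bool = True,
) -> DerivativeModel:
    """Run the build stage end to end on an in-memory ontology."""
    report = validate_graphs(onto)
    if report.cycles:
        from .core import CycleError

        raise CycleError(tuple(report.cycles[0][:2]))
    anat, idx = extract_anatomy_graph(onto)
    neo = extract_neoplasm_graph(onto)
    axis = build_morphology_axis(neo, namespace=namespace)
    refined = compute_refined_index(neo, axis)
    topos = collect_topographies(neo, idx, ancestor_completion=ancestor_completion)
    rp = build_rp_lattice(topos, idx, namespace=namespace)
    candidates = generate_candidates(axis, rp)
    retained = retain_diagnoses(candidates, refined, axis, idx, rp, namespace=namespace)
    dx = build_dx_lattice(retained, axis, idx, namespace=namespace)
    n_candidates = len(axis.candidate_morph_ids()) * len(rp)
    return DerivativeModel(onto, anat, idx, neo, axis, refined, rp, dx, n_candidates)


def bind_terminologies(
    model: DerivativeModel,
    crosswalk: CuiCrosswalk,
    icd10_codes,
    topo_codes,
    morph_codes,
) -> Bindings:
    """Instantiate the model with every code of the three lists."""
    b = Bindings()
    for tc in topo_codes:
        code = tc.code if hasattr(tc, "code") else tc
        b.topo[code] = bind_topography(code, crosswalk, model.onto, model.rp, model.idx)
    for tc in morph_codes:
        code = tc.code if hasattr(tc, "code") else tc
        b.morph[code] = bind_morphology(code, model.axis)
    for tc in icd10_codes:
        b.icd10[tc.code if hasattr(tc, "code") else tc] = bind_icd10(
            tc, crosswalk, model.onto, model.refined, model.dx, model.axis, model.idx
        )
    return b


def _audit_stage(model: DerivativeModel, bindings: Bindings) -> AuditReport:
    report = multi_instantiation_report(bindings.all())
    report.flags = behavior_conflicts(bindings.all(), model.dx, model.axis)
    report.flags += inconsistency_hypotheses(bindings.all(), model.idx)
    return report


def _evaluate_stage(model: DerivativeModel, bindings: Bindings, gold) -> EvalReport:
    combo_minimal: dict[tuple[str, str], list[tuple[str, str]]] = {}
    combo_satisfied: dict[tuple[str, str], set[tuple[str, str]]] = {}
    shared: dict[tuple[str, str, str], object] = {}
    from .core import dx_subsumes, minimal_elements
    from .evaluation import NOT_EVALUABLE

    def leq(k1, k2):
        return dx_subsumes(model.dx.classes[k1], model.dx.classes[k2], model.axis, model.idx)

    for row in gold:
        tb = bindings.topo.get(row.topo_code)
        mb = bindings.morph.get(row.morph_code)
        ib = bindings.icd10.get(row.icd10_code)
        key3 = (row.topo_code, row.morph_code, row.icd10_code)
        if tb is None or mb is None or ib is None or not (tb.bound and mb.bound and ib.bound):
            shared[key3] = NOT_EVALUABLE
            continue
        ckey = (row.topo_code, row.morph_code)
        if ckey not in combo_satisfied:
            sat = satisfied_dx_of_combination(tb, mb, model.dx, model.axis, model.idx)
            combo_satisfied[ckey] = sat
            combo_minimal[ckey] = minimal_elements(sat, leq)
        shared[key3] = shared_branches(
            ib, combo_satisfied[ckey], model.dx, model.axis, model.idx
        )
    predictions = rebuild_mappings(bindings.icd10, combo_minimal, model.dx)
    return evaluate(gold, predictions, shared)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute build -> bind -> audit -> evaluate; write all artifacts.

    Returns a summary dictionary of stage counts.  Raises on fatal stage
    errors; a missing gold file only skips the evaluation stage.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.artifact_header()
    log.info("pipeline start: %s", header)
    log.info("config: %s", json.dumps(config.model_dump(), sort_keys=True))

    onto = load_source_ontology(
        config.ontology_path, config.ontology_dialect,
        anatomy_root=config.anatomy_root, neoplasm_root=config.neoplasm_root,
    )
    if config.collapse_cycles:
        from .ingest import collapse_cycles

        onto = collapse_cycles(onto)
    model = build_model(
        onto, namespace=config.namespace,
        ancestor_completion=config.ancestor_completion,
    )
    log.info(
        "build: %d topographies, %d morphology classes, %d candidates, %d retained",
        len(model.rp), len(model.axis), model.n_candidates, len(model.dx),
    )
    from .export import serialize_derivative_model, write_bindings_tsv

    serialize_derivative_model(model, out / "derivative_model.ttl")

    summary = {
        "n_topographies": len(model.rp),
        "n_morphologies": len(model.axis) - 1,  # behavior classes + specific
        "n_candidates": model.n_candidates,
        "n_retained": len(model.dx),
    }

    bindings = None
    if config.crosswalk_path:
        crosswalk = CuiCrosswalk(
            read_cui_map(config.crosswalk_path, config.crosswalk_dialect)
        )
        icd10 = read_terminology(config.icd10_path, System.ICD10) if config.icd10_path else []
        topo = read_terminology(config.icdo3_topo_path, System.ICDO3_T) if config.icdo3_topo_path else []
        morph = read_terminology(config.icdo3_morph_path, System.ICDO3_M) if config.icdo3_morph_path else []
        bindings = bind_terminologies(model, crosswalk, icd10, topo, morph)
        write_bindings_tsv(bindings, out / "bindings.tsv", header)
        audit_report = _audit_stage(model, bindings)
        write_audit_tsv(audit_report, out / "audit.tsv", header)
        write_audit_json(audit_report, out / "audit.json", header)
        summary["n_bound_icd10"] = sum(1 for b in bindings.icd10.values() if b.bound)
        summary["n_bound_topo"] = sum(1 for b in bindings.topo.values() if b.bound)
        summary["n_bound_morph"] = sum(1 for b in bindings.morph.values() if b.bound)
        summary["n_conflicts"] = len(audit_report.flags)
    else:
        log.info("bind/audit skipped: no crosswalk configured")

    if config.seer_path and bindings is not None:
        gold, dropped = read_seer_conversion(config.seer_path)
        eval_report = _evaluate_stage(model, bindings, gold)
        write_eval_tsv(eval_report, out / "evaluation.tsv", header)
        write_eval_json(eval_report, out / "evaluation.json", header)
        summary["n_gold"] = len(gold)
        summary["n_gold_dropped"] = dropped
        summary["n_evaluable"] = eval_report.total.n_evaluable
        summary["n_related"] = eval_report.total.n_related
        summary["n_rebuilt"] = eval_report.total.n_rebuilt
    else:
        log.info("evaluate skipped: no gold standard configured")

    log.info("pipeline done in %.2fs", time.time() - t0)
    (out / "summary.json").write_text(
        json.dumps({"meta": header, **summary}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return summary
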