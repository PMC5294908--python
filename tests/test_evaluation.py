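"""Gold-standard reading, branch sharing, edge distances, rebuilds."""

import itertools
import math

import pytest

from dxlattice import fixtures as fx
from dxlattice.core import closure_of_edges, minimal_elements, dx_subsumes
from dxlattice.evaluation import (
    NOT_EVALUABLE,
    Stratum,
    dx_edge_distance,
    evaluate,
    read_seer_conversion,
    rebuild_mappings,
    shared_branches,
)
from dxlattice.terminology import satisfied_dx_of_combination


@pytest.fixture(scope="module")
def gold_file(tmp_path_factory, bundle):
    from dxlattice.fixtures import write_fixture_files

    root = tmp_path_factory.mktemp("gold")
    return write_fixture_files(bundle, root)["seer_gold.tsv"]


def test_read_seer_drops_out_of_scope_rows(gold_file, bundle):
    gold, dropped = read_seer_conversion(gold_file)
    assert len(gold) + dropped == len(bundle.gold)
    assert dropped == 1  # the /6 metastatic row
    assert all(row.stratum is Stratum.SOLID for row in gold)


def test_read_seer_stratum_assignment(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text(
        "topography\tmorphology\ticd10\n"
        "C42.1\t9732/3\tC90.0\n"   # myeloma: heme by both code and morphology
        "C50.9\t8140/3\tC50.9\n"
    )
    gold, _ = read_seer_conversion(p)
    assert [g.stratum for g in gold] == [Stratum.HEMATOPOIETIC, Stratum.SOLID]


def test_empty_gold(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("topography\tmorphology\ticd10\n")
    assert read_seer_conversion(p) == ([], 0)


class TestSharedBranches:
    def test_model_relates_pair_absent_from_gold(self, bindings, model):
        """The rectosigmoid code shares a branch with the colon+adenocarcinoma
        combination even though no gold row links them."""
        sat = satisfied_dx_of_combination(
            bindings.topo["C18.9"], bindings.morph["8140/3"],
            model.dx, model.axis, model.idx,
        )
        got = shared_branches(bindings.icd10["C19.9"], sat, model.dx, model.axis, model.idx)
        assert got == [("MALIGNANT_PRIMARY", fx.LARGE_INTESTINE)]

    def test_unbound_side_marks_not_evaluable(self, bindings, model):
        got = shared_branches(bindings.icd10["C00.1"], set(), model.dx, model.axis, model.idx)
        assert got == NOT_EVALUABLE

    def test_disjoint_sets_share_nothing(self, bindings, model):
        sat = satisfied_dx_of_combination(
            bindings.topo["C18.9"], bindings.morph["9121/0"],
            model.dx, model.axis, model.idx,
        )
        assert shared_branches(bindings.icd10["C50.9"], sat, model.dx, model.axis, model.idx) == []

    def test_result_is_antichain(self, bindings, model):
        sat = satisfied_dx_of_combination(
            bindings.topo["C18.8"], bindings.morph["8140/3"],
            model.dx, model.axis, model.idx,
        )
        got = shared_branches(bindings.icd10["C18.0"], sat, model.dx, model.axis, model.idx)
        assert len(got) == 2  # colon and colorectal branches
        for a, b in itertools.permutations(got, 2):
            assert not dx_subsumes(model.dx.classes[a], model.dx.classes[b],
                                   model.axis, model.idx)


class TestEdgeDistance:
    def test_identity(self, model):
        k = ("8140/3", fx.BREAST)
        assert dx_edge_distance(k, k, model.dx) == 0

    def test_parent_child_distance_one(self, model):
        assert dx_edge_distance(
            ("8140/3", fx.BREAST), ("MALIGNANT_PRIMARY", fx.BREAST), model.dx
        ) == 1

    def test_symmetry(self, model):
        keys = model.dx.keys()[:12]
        for k1, k2 in itertools.combinations(keys, 2):
            assert dx_edge_distance(k1, k2, model.dx) == dx_edge_distance(k2, k1, model.dx)

    def test_no_common_ancestor_is_infinite(self, model):
        # benign and malignant branches never meet (no top element)
        assert math.isinf(
            dx_edge_distance(("9121/0", fx.COLON), ("8140/3", fx.BREAST), model.dx)
        )

    def test_matches_exhaustive_common_ancestor_enumeration(self, model):
        closure = closure_of_edges(model.dx.keys(), model.dx.direct_edges)
        up = {}
        for k in model.dx.keys():
            up[k] = {t for (s, t) in closure if s == k}

        def brute(k1, k2):
            best = math.inf
            for z in up[k1] & up[k2]:
                d = _hasse_steps(model, k1, z) + _hasse_steps(model, k2, z)
                best = min(best, d)
            return best

        keys = model.dx.keys()
        for k1, k2 in itertools.combinations(keys[:15], 2):
            assert dx_edge_distance(k1, k2, model.dx) == brute(k1, k2)


def _hasse_steps(model, start, goal):
    """Shortest up-path length on the Hasse diagram, by plain BFS."""
    from collections import deque

    q = deque([(start, 0)])
    seen = {start}
    while q:
        node, d = q.popleft()
        if node == goal:
            return d
        for (s, t) in model.dx.direct_edges:
            if s == node and t not in seen:
                seen.add(t)
                q.append((t, d + 1))
    return math.inf


@pytest.fixture(scope="module")
def combos(bindings, model):
    def leq(k1, k2):
        return dx_subsumes(model.dx.classes[k1], model.dx.classes[k2],
                           model.axis, model.idx)

    out = {}
    for topo, morph in [("C18.0", "8140/3"), ("C18.9", "8140/3"),
                        ("C50.9", "8140/3"), ("C50.5", "8140/3"),
                        ("C50.9", "8010/2")]:
        sat = satisfied_dx_of_combination(
            bindings.topo[topo], bindings.morph[morph],
            model.dx, model.axis, model.idx,
        )
        out[(topo, morph)] = minimal_elements(sat, leq)
    return out


class TestRebuildAndEvaluate:
    def test_unique_nearest_code_predicted(self, bindings, model, combos):
        preds = rebuild_mappings(bindings.icd10, combos, model.dx)
        assert preds[("C18.0", "8140/3")].predicted == ("C18.0",)
        assert preds[("C50.9", "8140/3")].predicted == ("C50.9",)
        assert preds[("C50.9", "8010/2")].predicted == ("D05",)

    def test_tied_codes_all_predicted(self, bindings, model, combos):
        # colon-NOS adenocarcinoma sits one step from both the cecum code
        # (which also instantiates the colon branch) and the colon code
        pred = rebuild_mappings(bindings.icd10, combos, model.dx)[("C18.9", "8140/3")]
        assert set(pred.predicted) == {"C18.0", "C18.9"}

    def test_evaluate_fixture_gold(self, bindings, model, gold_file):
        from dxlattice.pipeline import _evaluate_stage
        from dxlattice.evaluation import read_seer_conversion

        gold, _ = read_seer_conversion(gold_file)
        report = _evaluate_stage(model, bindings, gold)
        assert report.total.n_evaluable == len(gold)
        assert report.total.n_related == report.total.n_evaluable  # 100%
        assert report.total.n_rebuilt <= report.total.n_related
        assert report.total.n_multibranch == 1  # the overlapping-lesion row
        # stratum counts sum to totals
        for field in ("n_evaluable", "n_related", "n_multibranch", "n_rebuilt",
                      "n_nonunique"):
            assert getattr(report.total, field) == sum(
                getattr(c, field) for c in report.by_stratum.values()
            )

    def test_evaluate_empty_gold(self, bindings, model):
        from dxlattice.pipeline import _evaluate_stage

        report = _evaluate_stage(model, bindings, [])
        assert report.total.n_evaluable == 0
        assert report.total.n_related == 0
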