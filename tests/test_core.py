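"""Order-engine unit and property tests."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from dxlattice import fixtures as fx
from dxlattice.core import (
    AnatomyIndex,
    CycleError,
    UnknownIdError,
    anat_reachable,
    closure_of_edges,
    dx_subsumes,
    minimal_elements,
    morph_subsumes,
    transitive_reduction,
)


class TestAnatReachability:
    @pytest.mark.parametrize(
        "s,t,expected",
        [
            (fx.CECUM, fx.LARGE_INTESTINE, True),   # part chain
            (fx.CECUM, fx.CECUM, True),             # reflexivity
            (fx.COLON, fx.COLORECTAL, False),       # no part/is_a link either way
            (fx.COLORECTAL, fx.COLON, False),
            (fx.BIRBECK_GRANULE, fx.SKIN, True),    # cell-level partonomy chain
            (fx.LOQ_BREAST, fx.BREAST, True),
            (fx.RECTOSIGMOID, fx.GI_SYSTEM, True),  # mixed part roles compose
            (fx.BREAST, fx.LOQ_BREAST, False),      # not symmetric
        ],
    )
    def test_fixture_reachability(self, model, s, t, expected):
        assert anat_reachable(s, t, model.idx) is expected

    def test_reflexive_for_every_node(self, model):
        assert all(anat_reachable(n, n, model.idx) for n in model.idx.nodes())

    def test_unknown_id_raises(self, model):
        with pytest.raises(UnknownIdError, match="NCIT:NOPE"):
            anat_reachable("NCIT:NOPE", fx.SKIN, model.idx)
        with pytest.raises(UnknownIdError):
            anat_reachable(fx.SKIN, "NCIT:NOPE", model.idx)

    def test_cycle_in_anatomy_edges_rejected(self):
        with pytest.raises(CycleError):
            AnatomyIndex(["a", "b"], [("a", "b"), ("b", "a")])

    def test_transitivity_on_fixture(self, model):
        nodes = model.idx.nodes()
        for s in nodes:
            for t in model.idx.up_set(s):
                for u in model.idx.up_set(t):
                    assert anat_reachable(s, u, model.idx)


class TestMorphSubsumption:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("8140/3", "MALIGNANT_PRIMARY", True),  # behavior digit /3
            ("8140/3", "8140/3", True),
            ("9121/0", "9120/0", False),  # specific morphologies are incomparable
            ("9120/0", "9121/0", False),
            ("9121/0", "BENIGN", True),
            ("8010/2", "MALIGNANT_PRIMARY", False),  # behavior mismatch
            ("MALIGNANT_PRIMARY", "8140/3", False),  # not downward
            ("BENIGN", "MORPH:ROOT", True),
            ("MORPH:ROOT", "BENIGN", False),
        ],
    )
    def test_fixture_pairs(self, model, a, b, expected):
        assert morph_subsumes(a, b, model.axis) is expected

    def test_unknown_morph_raises(self, model):
        with pytest.raises(UnknownIdError):
            morph_subsumes("1234/3", "BENIGN", model.axis)


class TestDxSubsumption:
    def test_specific_below_behavior_level(self, model):
        d1 = model.dx.classes[("8140/3", fx.LOQ_BREAST)]
        d2 = model.dx.classes[("MALIGNANT_PRIMARY", fx.LOQ_BREAST)]
        assert dx_subsumes(d1, d2, model.axis, model.idx)
        assert not dx_subsumes(d2, d1, model.axis, model.idx)

    def test_reflexive(self, model):
        for key in model.dx.keys():
            d = model.dx.classes[key]
            assert dx_subsumes(d, d, model.axis, model.idx)

    def test_incomparable_sites_not_subsumed(self, model):
        d1 = model.dx.classes[("MALIGNANT_PRIMARY", fx.CECUM)]
        d2 = model.dx.classes[("MALIGNANT_PRIMARY", fx.COLORECTAL)]
        assert not dx_subsumes(d1, d2, model.axis, model.idx)
        assert not dx_subsumes(d2, d1, model.axis, model.idx)


def _leq_from_pairs(pairs):
    return lambda x, y: x == y or (x, y) in pairs


class TestTransitiveReduction:
    def test_chain_reduces_to_cover_edges(self):
        pairs = {("a", "b"), ("b", "c"), ("a", "c")}
        assert transitive_reduction("abc", _leq_from_pairs(pairs)) == {
            ("a", "b"),
            ("b", "c"),
        }

    def test_antichain_has_no_edges(self):
        assert transitive_reduction(["x", "y", "z"], lambda a, b: a == b) == set()

    def test_cycle_reported_with_offending_pair(self):
        pairs = {("a", "b"), ("b", "a")}
        with pytest.raises(CycleError):
            transitive_reduction("ab", _leq_from_pairs(pairs))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_closure_round_trip_on_random_dags(self, seed):
        """closure(reduction(order)) == order for random 25-node DAG closures."""
        g = nx.gnp_random_graph(25, 0.15, seed=seed, directed=True)
        dag = nx.DiGraph((u, v) for u, v in g.edges() if u < v)
        dag.add_nodes_from(range(25))
        order = closure_of_edges(dag.nodes, dag.edges)
        reduced = transitive_reduction(range(25), _leq_from_pairs(order))
        assert closure_of_edges(range(25), reduced) == order
        # and it is minimal: dropping any edge loses part of the order
        for edge in reduced:
            smaller = closure_of_edges(range(25), reduced - {edge})
            assert smaller != order


class TestMinimalElements:
    def test_direct_type_shape_on_fixture(self, model):
        # C9329's five asserted sites: the three mutually unrelated ones are
        # minimal, the coarser containers are not
        keys = [
            ("MALIGNANT_PRIMARY", t)
            for t in (fx.CECUM, fx.COLON, fx.COLORECTAL, fx.INTESTINE, fx.GI_SYSTEM)
        ]

        def leq(k1, k2):
            return dx_subsumes(
                model.dx.classes[k1], model.dx.classes[k2], model.axis, model.idx
            )

        assert minimal_elements(keys, leq) == [
            ("MALIGNANT_PRIMARY", fx.CECUM),
            ("MALIGNANT_PRIMARY", fx.COLON),
            ("MALIGNANT_PRIMARY", fx.COLORECTAL),
        ]

    def test_singleton_and_empty(self):
        assert minimal_elements(["x"], lambda a, b: a == b) == ["x"]
        assert minimal_elements([], lambda a, b: True) == []

    def test_chain_keeps_bottom(self):
        pairs = {("a", "b"), ("b", "c"), ("a", "c")}
        assert minimal_elements("abc", _leq_from_pairs(pairs)) == ["a"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_result_is_always_an_antichain(self, seed):
        g = nx.gnp_random_graph(12, 0.3, seed=seed, directed=True)
        dag_edges = {(u, v) for u, v in g.edges() if u < v}
        order = closure_of_edges(range(12), dag_edges)
        leq = _leq_from_pairs(order)
        out = minimal_elements(range(12), leq)
        for x in out:
            for y in out:
                assert x == y or not (leq(x, y) or leq(y, x))
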