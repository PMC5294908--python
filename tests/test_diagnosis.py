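"""Candidate generation, retention and the diagnosis lattice."""

import itertools

import pytest

from dxlattice import fixtures as fx
from dxlattice.core import UnknownIdError, closure_of_edges, dx_subsumes
from dxlattice.diagnosis import (
    concept_satisfies,
    direct_dx_superclasses,
    generate_candidates,
)
from dxlattice.fixtures import GenParams, random_ontology
from dxlattice.oracle import brute_force_oracle
from dxlattice.pipeline import build_model


class TestCandidateGeneration:
    def test_cross_product_count(self, model):
        n = sum(1 for _ in generate_candidates(model.axis, model.rp))
        assert n == len(model.axis.candidate_morph_ids()) * len(model.rp)
        assert n == model.n_candidates

    def test_empty_lattice_streams_nothing(self):
        from dxlattice.morphology import MorphologyAxis
        from dxlattice.anatomy import RPLattice

        assert list(generate_candidates(MorphologyAxis(), RPLattice())) == []

    def test_stream_is_lazy(self, model):
        gen = generate_candidates(model.axis, model.rp)
        first = next(gen)
        assert isinstance(first, tuple) and len(first) == 2


class TestSatisfactionAndRetention:
    def test_breast_adenocarcinoma_example(self, model):
        assert concept_satisfies(
            fx.BREAST_ADENOCARCINOMA, ("8140/3", fx.BREAST),
            model.refined, model.axis, model.idx,
        )

    def test_c18_binding_reaches_colorectal_via_c9329_sites(self, bindings):
        # C9329 itself carries no morphology annotation, so the colorectal
        # class is reached only once the ICD-10 block behavior joins in
        assert ("MALIGNANT_PRIMARY", fx.COLORECTAL) in bindings.icd10[
            "C18.0"
        ].satisfied_classes

    def test_concept_without_morphology_satisfies_nothing(self, model):
        # C9329 carries sites but no inherited morphology annotation
        keys = [k for k in model.dx.keys()
                if concept_satisfies(fx.C9329, k, model.refined, model.axis, model.idx)]
        assert keys == []

    def test_unknown_concept_raises(self, model):
        with pytest.raises(UnknownIdError):
            concept_satisfies("NCIT:GHOST", ("8140/3", fx.BREAST),
                              model.refined, model.axis, model.idx)

    def test_retained_contains_cecum_malignant_class(self, model):
        key = ("MALIGNANT_PRIMARY", fx.CECUM)
        assert key in model.dx
        assert fx.CECUM_ADENOCARCINOMA in model.dx.classes[key].supporting_concepts

    def test_unsupported_candidate_not_retained(self, model):
        assert ("9121/0", fx.BREAST) not in model.dx

    def test_every_retained_class_has_support(self, model):
        for d in model.dx.classes.values():
            assert d.supporting_concepts

    def test_retention_equals_brute_force_double_loop(self, model):
        """Soundness and completeness of the indexed scan."""
        brute = set()
        for concept in model.refined.inherited_morphs:
            for cand in generate_candidates(model.axis, model.rp):
                if concept_satisfies(concept, cand, model.refined, model.axis, model.idx):
                    brute.add(cand)
        assert brute == set(model.dx.classes)

    def test_support_is_upward_closed(self, model):
        """A concept supporting a class supports everything above it."""
        closure = closure_of_edges(model.dx.keys(), model.dx.direct_edges)
        for sub, sup in closure:
            assert (
                model.dx.classes[sub].supporting_concepts
                <= model.dx.classes[sup].supporting_concepts
            )


class TestDxLattice:
    def test_hemangioma_pair_incomparable(self, model):
        d1 = model.dx.classes[("9121/0", fx.COLON)]
        d2 = model.dx.classes[("9120/0", fx.COLON)]
        assert not dx_subsumes(d1, d2, model.axis, model.idx)
        assert not dx_subsumes(d2, d1, model.axis, model.idx)

    def test_hasse_closure_equals_pairwise_order(self, model):
        closure = closure_of_edges(model.dx.keys(), model.dx.direct_edges)
        for k1, k2 in itertools.product(model.dx.keys(), repeat=2):
            expected = dx_subsumes(
                model.dx.classes[k1], model.dx.classes[k2], model.axis, model.idx
            )
            assert ((k1, k2) in closure) is expected

    def test_random_fixture_closure_matches_oracle(self):
        onto = random_ontology(GenParams(n_anatomy=10, n_neoplasm=10, n_morph=5, seed=3))
        m = build_model(onto)
        oracle = brute_force_oracle(onto)
        closure = closure_of_edges(m.dx.keys(), m.dx.direct_edges)
        for k1 in m.dx.keys():
            for k2 in m.dx.keys():
                assert ((k1, k2) in closure) is oracle.dx_leq(k1, k2)


class TestDirectSuperclasses:
    def test_colon_cavernous_hemangioma_four_expressions(self, model):
        got = {
            d.key
            for d in direct_dx_superclasses(
                fx.COLON_CAVERNOUS_HEMANGIOMA, model.dx, model.refined,
                model.axis, model.idx,
            )
        }
        assert got == {
            ("9121/0", fx.COLON), ("9121/0", fx.COLORECTAL),
            ("9120/0", fx.COLON), ("9120/0", fx.COLORECTAL),
        }

    def test_concept_satisfying_nothing_yields_empty(self, model):
        assert direct_dx_superclasses(
            fx.NEOPLASM_ROOT, model.dx, model.refined, model.axis, model.idx
        ) == []

    def test_result_is_an_antichain(self, model):
        for concept in (fx.COLON_CAVERNOUS_HEMANGIOMA, fx.C3641, fx.LOQ_ADENOCARCINOMA):
            direct = direct_dx_superclasses(
                concept, model.dx, model.refined, model.axis, model.idx
            )
            for a in direct:
                for b in direct:
                    if a.key != b.key:
                        assert not dx_subsumes(a, b, model.axis, model.idx)
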