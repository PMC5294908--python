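"""Terminology ingestion, crosswalk joins and code binding."""

import pytest

from dxlattice import fixtures as fx
from dxlattice.core import BehaviorClass, dx_subsumes
from dxlattice.terminology import (
    BindingStatus,
    CuiMapRecord,
    DxLatticeError,
    Excluded,
    System,
    derive_icd10_behavior,
    read_cui_map,
    read_terminology,
    satisfied_dx_of_combination,
)


class TestIcd10Behavior:
    @pytest.mark.parametrize(
        "code,behavior",
        [
            ("C50.9", BehaviorClass.MALIGNANT_PRIMARY),
            ("C00.1", BehaviorClass.MALIGNANT_PRIMARY),
            ("D05", BehaviorClass.IN_SITU),
            ("D12.6", BehaviorClass.BENIGN),
        ],
    )
    def test_block_lookup(self, code, behavior):
        assert derive_icd10_behavior(code) is behavior

    @pytest.mark.parametrize("code", ["D40", "C78.0", "Z99", "banana"])
    def test_out_of_scope_codes_excluded(self, code):
        assert isinstance(derive_icd10_behavior(code), Excluded)


class TestReaders:
    def test_read_terminology_populates_behavior(self, tmp_path):
        p = tmp_path / "codes.csv"
        p.write_text("code,label\n8140/3,Adenocarcinoma NOS\n8140/3,dup row\n")
        codes = read_terminology(p, System.ICDO3_M)
        assert len(codes) == 1  # duplicates collapsed
        assert codes[0].behavior is BehaviorClass.MALIGNANT_PRIMARY

    def test_read_terminology_icd10_in_situ(self, tmp_path):
        p = tmp_path / "codes.csv"
        p.write_text("code,label\nD05,Carcinoma in situ of breast\n")
        assert read_terminology(p, System.ICD10)[0].behavior is BehaviorClass.IN_SITU

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "codes.csv"
        p.write_text("code,label\n")
        assert read_terminology(p, System.ICD10) == []

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "codes.csv"
        p.write_text("C50.9,Breast\n")
        with pytest.raises(DxLatticeError):
            read_terminology(p, System.ICD10)

    def test_cui_map_rrf_and_tsv_agree(self, tmp_path):
        records = [
            CuiMapRecord("CUI1", "ICD10", "C50.9"),
            CuiMapRecord("CUI1", "NCI", "C9335"),
        ]
        tsv = tmp_path / "map.tsv"
        tsv.write_text(
            "cui\tsab\tcode\n" + "".join(f"{r.cui}\t{r.sab}\t{r.code}\n" for r in records)
        )
        # MRCONSO layout: CUI first, SAB at index 11, CODE at index 13
        rrf = tmp_path / "map.rrf"
        rows = []
        for r in records:
            fields = [""] * 18
            fields[0], fields[11], fields[13] = r.cui, r.sab, r.code
            rows.append("|".join(fields))
        rrf.write_text("\n".join(rows) + "\n")
        assert read_cui_map(tsv, "TSV") == read_cui_map(rrf, "RRF_PIPE")

    def test_cui_map_empty(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("cui\tsab\tcode\n")
        assert read_cui_map(p, "TSV") == []


class TestTopographyBinding:
    def test_loq_breast_code_binds_to_its_reflexive_part(self, bindings):
        b = bindings.topo["C50.5"]
        assert b.status is BindingStatus.BOUND
        assert b.direct_classes == (fx.LOQ_BREAST,)

    def test_non_anatomy_mapping_excluded(self, bindings):
        assert bindings.topo["C05.1"].status is BindingStatus.NON_ANATOMY_ONLY

    def test_code_without_crosswalk_row_unmapped(self, bindings):
        assert bindings.topo["C76.0"].status is BindingStatus.UNMAPPED

    def test_multi_cui_topography_binds_to_antichain(self, bindings, model):
        b = bindings.topo["C18.8"]
        assert set(b.direct_classes) == {fx.COLON, fx.COLORECTAL}
        for s in b.direct_classes:
            for t in b.direct_classes:
                assert s == t or not model.idx.leq(s, t)


class TestMorphologyBinding:
    def test_known_code_bound(self, bindings):
        assert bindings.morph["8140/3"].status is BindingStatus.BOUND

    def test_absent_code_unmapped(self, bindings):
        assert bindings.morph["9999/3"].status is BindingStatus.UNMAPPED


class TestIcd10Binding:
    def test_c509_single_behavior_level_class(self, bindings):
        assert bindings.icd10["C50.9"].direct_classes == (
            ("MALIGNANT_PRIMARY", fx.BREAST),
        )

    def test_c180_three_incomparable_sites(self, bindings):
        assert set(bindings.icd10["C18.0"].direct_classes) == {
            ("MALIGNANT_PRIMARY", fx.CECUM),
            ("MALIGNANT_PRIMARY", fx.COLON),
            ("MALIGNANT_PRIMARY", fx.COLORECTAL),
        }

    def test_d05_keeps_conflicting_morphologies(self, bindings):
        """The block behavior must not filter inherited morphologies."""
        assert set(bindings.icd10["D05"].direct_classes) == {
            ("8010/2", fx.BREAST),
            ("8010/3", fx.BREAST),
        }

    def test_unmapped_and_scope_statuses(self, bindings):
        assert bindings.icd10["C00.1"].status is BindingStatus.UNMAPPED
        assert bindings.icd10["D40"].status is BindingStatus.EXCLUDED_SCOPE
        assert bindings.icd10["C78.0"].status is BindingStatus.EXCLUDED_SCOPE

    def test_status_counts_conserved(self, bindings):
        for group in (bindings.icd10, bindings.topo, bindings.morph):
            by_status = {}
            for b in group.values():
                by_status[b.status] = by_status.get(b.status, 0) + 1
            assert sum(by_status.values()) == len(group)

    def test_direct_classes_are_antichains(self, bindings, model):
        for b in bindings.icd10.values():
            for k1 in b.direct_classes:
                for k2 in b.direct_classes:
                    if k1 != k2:
                        assert not dx_subsumes(
                            model.dx.classes[k1], model.dx.classes[k2],
                            model.axis, model.idx,
                        )


class TestCombinationSatisfaction:
    def test_colon_adenocarcinoma_reaches_large_intestine(self, bindings, model):
        sat = satisfied_dx_of_combination(
            bindings.topo["C18.9"], bindings.morph["8140/3"],
            model.dx, model.axis, model.idx,
        )
        assert ("MALIGNANT_PRIMARY", fx.LARGE_INTESTINE) in sat

    def test_unbound_input_is_an_error(self, bindings, model):
        with pytest.raises(DxLatticeError):
            satisfied_dx_of_combination(
                bindings.topo["C05.1"], bindings.morph["8140/3"],
                model.dx, model.axis, model.idx,
            )

    def test_satisfied_set_upward_closed(self, bindings, model):
        sat = satisfied_dx_of_combination(
            bindings.topo["C18.9"], bindings.morph["8140/3"],
            model.dx, model.axis, model.idx,
        )
        for key in sat:
            for other in model.dx.keys():
                if dx_subsumes(
                    model.dx.classes[key], model.dx.classes[other],
                    model.axis, model.idx,
                ):
                    assert other in sat
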