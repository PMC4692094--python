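"""Skyline report parsing and conversion rules: header dialect, null
convention, label-mode detection, document construction counts, lossless
measurement transfer."""

import pytest
from hypothesis import given, settings, strategies as st

from srmzq.model import Label, LabelMode
from srmzq.skyline_import import (
    ReportError,
    ReportRow,
    build_document,
    detect_label_mode,
    parse_report,
    split_modified_sequence,
)
from srmzq.validate import has_errors, validate_document

from conftest import make_experiment

HEADER = (
    "ProteinName,PeptideModifiedSequence,PrecursorMz,PrecursorCharge,"
    "ProductMz,ProductCharge,FragmentIon,IsotopeLabelType,ReplicateName,"
    "FileName,RetentionTime,Area,Background,Height,Fwhm"
)


def _row(
    protein="P1",
    peptide="PEPTIDEK",
    prec_mz="500.1",
    prec_z="2",
    prod_mz="601.2",
    prod_z="1",
    fragment="y5",
    label="light",
    replicate="rep_1",
    filename="r1.raw",
    rt="12.5",
    area="1000",
    background="10",
    height="500",
    fwhm="0.1",
):
    return ",".join(
        [protein, peptide, prec_mz, prec_z, prod_mz, prod_z, fragment, label,
         replicate, filename, rt, area, background, height, fwhm]
    )


def _csv(*rows):
    return HEADER + "\n" + "\n".join(rows) + "\n"


class TestParseReport:
    def test_single_light_row(self):
        rows = parse_report(_csv(_row()))
        assert len(rows) == 1
        assert rows[0].label is Label.LIGHT
        assert rows[0].area == 1000.0

    def test_header_only_gives_empty_list(self):
        assert parse_report(HEADER + "\n") == []

    def test_header_match_ignores_case_and_spaces(self):
        spaced = (
            "Protein Name,Peptide Modified Sequence,Precursor Mz,"
            "precursor charge,Product Mz,Product Charge,Fragment Ion,"
            "Isotope Label Type,Replicate Name,File Name,Retention Time,"
            "area,BACKGROUND,Height,fwhm"
        )
        rows = parse_report(spaced + "\n" + _row() + "\n")
        assert rows[0].peptide_modified_sequence == "PEPTIDEK"

    @pytest.mark.parametrize("cell", ["", "#N/A"])
    def test_blank_and_na_numeric_cells_become_absent(self, cell):
        rows = parse_report(_csv(_row(rt=cell, area=cell)))
        assert rows[0].retention_time is None
        assert rows[0].area is None

    def test_missing_column_error_lists_names(self):
        headless = HEADER.replace("IsotopeLabelType,", "")
        body = _row().replace("light,", "")
        with pytest.raises(ReportError, match="isotope_label_type"):
            parse_report(headless + "\n" + body + "\n")

    def test_unparseable_numeric_cell_names_row_and_column(self):
        with pytest.raises(ReportError, match="row 3.*area"):
            parse_report(_csv(_row(), _row(fragment="y6", area="oops")))

    def test_bad_label_value_rejected(self):
        with pytest.raises(ReportError, match="light.*heavy"):
            parse_report(_csv(_row(label="medium")))


class TestDetectLabelMode:
    def test_all_light_is_label_free(self):
        rows = parse_report(_csv(_row(), _row(fragment="y6")))
        assert detect_label_mode(rows) is LabelMode.LABEL_FREE

    def test_mixed_labels_is_label_based(self):
        rows = parse_report(_csv(_row(), _row(label="heavy")))
        assert detect_label_mode(rows) is LabelMode.MS1_LABEL_BASED

    def test_all_heavy_is_label_based(self):
        rows = parse_report(_csv(_row(label="heavy")))
        assert detect_label_mode(rows) is LabelMode.MS1_LABEL_BASED

    def test_empty_input_is_an_error(self):
        with pytest.raises(ReportError):
            detect_label_mode([])

    @given(st.lists(st.sampled_from(["light", "heavy"]), min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=50)
    def test_label_free_iff_every_row_light(self, labels):
        rows = [
            ReportRow(
                protein_name="P1",
                peptide_modified_sequence="PEPTIDEK",
                precursor_mz=500.0,
                precursor_charge=2,
                product_mz=600.0,
                product_charge=1,
                fragment_ion=f"y{i}",
                isotope_label_type=label,
                replicate_name="rep_1",
                file_name="r1.raw",
            )
            for i, label in enumerate(labels)
        ]
        expected = (
            LabelMode.LABEL_FREE
            if all(l == "light" for l in labels)
            else LabelMode.MS1_LABEL_BASED
        )
        assert detect_label_mode(rows) is expected


class TestModifiedSequence:
    @pytest.mark.parametrize(
        "modseq,sequence,descriptor",
        [
            ("PEPTIDEK", "PEPTIDEK", ""),
            ("PEPT[+80]IDEK", "PEPTIDEK", "4:+80"),
            ("[Acetyl]MPEPK", "MPEPK", "0:Acetyl"),
            ("C[+57]PEC[+57]K", "CPECK", "1:+57;4:+57"),
        ],
    )
    def test_canonical_descriptor(self, modseq, sequence, descriptor):
        assert split_modified_sequence(modseq) == (sequence, descriptor)

    def test_unbalanced_bracket_rejected(self):
        with pytest.raises(ReportError):
            split_modified_sequence("PEP[80TIDE")


class TestBuildDocument:
    def test_label_free_two_replicates_counts(self):
        rows = []
        for rep in ("rep_1", "rep_2"):
            for i in range(3):
                rows.append(_row(fragment=f"y{i+3}", prod_mz=f"60{i}.5",
                                 replicate=rep, filename=f"{rep}.raw"))
        doc = build_document(parse_report(_csv(*rows)))
        assert len(doc.assays) == 2
        assert sum(len(fl.features) for fl in doc.feature_lists) == 6
        assert len(doc.peptides) == 1
        assert doc.ratio_definitions == [] and doc.ratio_quant_layer is None

    def test_labeled_doubles_assays_and_adds_ratios(self):
        rows = []
        for rep in ("rep_1", "rep_2"):
            for label in ("light", "heavy"):
                for i in range(3):
                    rows.append(_row(fragment=f"y{i+3}", label=label,
                                     replicate=rep, filename=f"{rep}.raw"))
        doc = build_document(parse_report(_csv(*rows)))
        assert len(doc.assays) == 4
        assert sum(len(fl.features) for fl in doc.feature_lists) == 12
        assert len(doc.peptides) == 1
        assert len(doc.ratio_definitions) == 2
        assert doc.ratio_quant_layer is not None

    def test_feature_quant_layer_has_four_fixed_columns(self, label_free_doc):
        for fl in label_free_doc.feature_lists:
            for layer in fl.quant_layers:
                names = [c.datatype.name for c in layer.columns]
                assert names == [
                    "XIC area", "XIC background", "XIC height",
                    "full width at half-maximum",
                ]

    def test_duplicate_transition_instance_is_ambiguous(self):
        with pytest.raises(ReportError, match="ambiguous feature"):
            build_document(parse_report(_csv(_row(), _row())))

    def test_absent_area_becomes_zero_but_feature_exists(self):
        doc = build_document(parse_report(_csv(_row(area="#N/A"))))
        layer = doc.feature_lists[0].quant_layers[0]
        assert list(layer.rows.values()) == [[0.0, 10.0, 500.0, 0.1]]
        assert len(doc.feature_lists[0].features) == 1

    def test_precursor_rt_is_always_null(self, labeled_doc):
        for fl in labeled_doc.feature_lists:
            for ft in fl.features:
                assert ft.precursor_rt is None

    def test_feature_count_matches_independent_key_set(self):
        _result, rows, doc = make_experiment(seed=21, labeled=True,
                                             noise_sigma=0.2)
        keys = {
            (r.replicate_name, r.peptide_modified_sequence, r.precursor_charge,
             r.fragment_ion, r.product_charge, r.label)
            for r in rows
        }
        assert sum(len(fl.features) for fl in doc.feature_lists) == len(keys)

    def test_lossless_measurement_transfer(self):
        _result, rows, doc = make_experiment(seed=22, labeled=True,
                                             noise_sigma=0.3)
        emitted = []
        for fl in doc.feature_lists:
            for layer in fl.quant_layers:
                emitted.extend(tuple(v) for v in layer.rows.values())
        expected = [
            (r.area or 0.0, r.background or 0.0, r.height or 0.0, r.fwhm or 0.0)
            for r in rows
        ]
        assert sorted(emitted) == sorted(expected)
        assert len(emitted) == len(expected)

    def test_converter_output_validates_clean(self, corpus):
        for _result, doc in corpus[:20]:
            assert not has_errors(validate_document(doc))

    def test_empty_input_rejected(self):
        with pytest.raises(ReportError):
            build_document([])
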