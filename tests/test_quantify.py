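"""Aggregation arithmetic against hand-computed and brute-force oracles,
ratio semantics, conservation and permutation invariance."""

import math
import random

import pytest

from srmzq.model import LabelMode
from srmzq.quantify import (
    AggregationSpec,
    PeptideMethod,
    ProteinMethod,
    aggregate_peptides,
    aggregate_proteins,
    compute_peptide_ratios,
)
from srmzq.skyline_import import build_document, parse_report

from conftest import make_experiment
from test_skyline_import import _csv, _row


def _three_transition_doc(method, areas=("100", "200", "300")):
    rows = [
        _row(fragment=f"y{i+3}", prod_mz=f"60{i}.5", area=a)
        for i, a in enumerate(areas)
    ]
    spec = AggregationSpec(peptide_method=method)
    return build_document(parse_report(_csv(*rows)), spec=spec)


class TestAggregatePeptides:
    def test_sum_of_three_transitions(self):
        doc = _three_transition_doc(PeptideMethod.SUM)
        assert list(doc.peptide_quant_layers[0].rows.values()) == [[600.0]]

    def test_mean_of_three_transitions(self):
        doc = _three_transition_doc(PeptideMethod.MEAN)
        assert list(doc.peptide_quant_layers[0].rows.values()) == [[200.0]]

    def test_weighted_mean_weighted_by_area(self):
        # oracle: sum(w*x)/sum(w) with w = x = {100,200,300}
        expected = (100**2 + 200**2 + 300**2) / 600
        doc = _three_transition_doc(PeptideMethod.WEIGHTED_MEAN)
        value = doc.peptide_quant_layers[0].rows[doc.peptides[0].id][0]
        assert value == pytest.approx(expected)
        assert value == pytest.approx(233.3333333, abs=1e-6)

    @pytest.mark.parametrize("method", list(PeptideMethod))
    def test_single_transition_is_identity(self, method):
        doc = _three_transition_doc(method, areas=("123.5",))
        assert list(doc.peptide_quant_layers[0].rows.values()) == [[123.5]]

    def test_all_zero_weights_give_zero_and_warning(self):
        doc = _three_transition_doc(
            PeptideMethod.WEIGHTED_MEAN, areas=("0", "0", "0")
        )
        layer = doc.peptide_quant_layers[0]
        assert list(layer.rows.values()) == [[0.0]]
        assert any(f.rule_id == "Q1" for f in layer.findings)

    def test_datatype_records_method(self):
        doc = _three_transition_doc(PeptideMethod.MEAN)
        assert doc.peptide_quant_layers[0].datatype.name == "mean XIC area"

    def test_peptide_absent_from_assay_quantifies_zero(self):
        rows = [
            _row(),
            _row(peptide="AAAGHIKR", prec_mz="432.1", fragment="y4",
                 replicate="rep_2", filename="rep_2.raw"),
        ]
        doc = build_document(parse_report(_csv(*rows)))
        layer = doc.peptide_quant_layers[0]
        assert layer.rows["pep_0"] == [1000.0, 0.0]
        assert layer.rows["pep_1"] == [0.0, 1000.0]

    def test_weight_column_only_for_weighted_mean(self):
        with pytest.raises(ValueError):
            AggregationSpec(peptide_method=PeptideMethod.SUM, weight_column="XIC area")
        spec = AggregationSpec(peptide_method=PeptideMethod.WEIGHTED_MEAN)
        assert spec.weight_column == "XIC area"


class TestRatios:
    def _labeled_doc(self, light_areas, heavy_areas):
        rows = []
        for label, areas in (("light", light_areas), ("heavy", heavy_areas)):
            for i, a in enumerate(areas):
                rows.append(_row(fragment=f"y{i+3}", label=label, area=a))
        return build_document(parse_report(_csv(*rows)))

    def test_light_600_heavy_300_gives_two(self):
        doc = self._labeled_doc(("100", "200", "300"), ("50", "100", "150"))
        assert list(doc.ratio_quant_layer.rows.values()) == [[2.0]]

    def test_zero_light_gives_zero(self):
        doc = self._labeled_doc(("0",), ("300",))
        assert list(doc.ratio_quant_layer.rows.values()) == [[0.0]]

    def test_zero_heavy_gives_nan_with_warning(self):
        doc = self._labeled_doc(("600",), ("0",))
        value = next(iter(doc.ratio_quant_layer.rows.values()))[0]
        assert math.isnan(value)
        assert any(f.rule_id == "Q2" for f in doc.ratio_quant_layer.findings)

    def test_label_free_document_refused(self, label_free_doc):
        with pytest.raises(ValueError, match="label-free"):
            compute_peptide_ratios(
                label_free_doc, label_free_doc.peptide_quant_layers[0]
            )

    def test_numerator_is_light_by_default_and_flippable(self):
        doc = self._labeled_doc(("600",), ("300",))
        ratio = doc.ratio_definitions[0]
        num = doc.assay_by_id(ratio.numerator_ref)
        den = doc.assay_by_id(ratio.denominator_ref)
        assert num.name.endswith("_light") and den.name.endswith("_heavy")

        rows = [_row(area="600"), _row(label="heavy", area="300")]
        flipped = build_document(parse_report(_csv(*rows)), flip_ratio=True)
        assert list(flipped.ratio_quant_layer.rows.values()) == [[0.5]]

    def test_noise_free_generator_recovers_true_ratio_exactly(self):
        result, _rows, doc = make_experiment(seed=31, labeled=True,
                                             noise_sigma=0.0, true_ratio=2.0)
        for values in doc.ratio_quant_layer.rows.values():
            assert values == [2.0] * len(values)
        for pep in result.truth.values():
            assert all(r == 2.0 for r in pep.ratios.values())

    def test_median_ratio_recovery_under_lognormal_noise(self):
        # multiplicative noise sigma on areas, n transitions per peptide:
        # the pooled median peptide ratio stays within 3*sigma/sqrt(n) of truth
        sigma, n_transitions, true_ratio = 0.2, 5, 2.0
        ratios = []
        for seed in range(20):
            _result, _rows, doc = make_experiment(
                seed=100 + seed, labeled=True, noise_sigma=sigma,
                transitions_per_peptide=n_transitions, true_ratio=true_ratio,
            )
            for values in doc.ratio_quant_layer.rows.values():
                ratios.extend(values)
        ratios.sort()
        median = ratios[len(ratios) // 2]
        assert abs(median - true_ratio) <= 3 * sigma / math.sqrt(n_transitions)


class TestAggregateProteins:
    def test_mean_of_two_peptides(self):
        rows = [
            _row(area="600"),
            _row(peptide="AAAGHIKR", prec_mz="432.1", fragment="y4", area="400"),
        ]
        doc = build_document(parse_report(_csv(*rows)))
        layer = aggregate_proteins(
            doc, doc.peptide_quant_layers[0],
            AggregationSpec(protein_method=ProteinMethod.MEAN),
        )
        assert list(layer.rows.values()) == [[500.0]]

    def test_single_peptide_is_identity(self):
        doc = build_document(parse_report(_csv(_row(area="777"))))
        layer = aggregate_proteins(doc, doc.peptide_quant_layers[0])
        assert list(layer.rows.values()) == [[777.0]]

    def test_sum_equals_brute_force_over_peptides(self):
        _result, _rows, doc = make_experiment(seed=41, labeled=True,
                                              noise_sigma=0.25)
        pep_layer = doc.peptide_quant_layers[0]
        layer = aggregate_proteins(doc, pep_layer)
        for prot in doc.proteins:
            expected = [
                sum(pep_layer.rows[p][i] for p in prot.peptide_refs)
                for i in range(len(pep_layer.assay_refs))
            ]
            assert layer.rows[prot.id] == pytest.approx(expected, rel=1e-12)

    def test_protein_without_peptides_excluded_with_warning(self, label_free_doc):
        orphan = label_free_doc.add_protein("ORPHAN")
        layer = aggregate_proteins(
            label_free_doc, label_free_doc.peptide_quant_layers[0]
        )
        assert orphan.id not in layer.rows
        assert any(f.rule_id == "Q3" for f in layer.findings)

    def test_conservation_under_sum(self):
        # total protein mass = total peptide mass = total XIC area, per assay
        _result, rows, doc = make_experiment(seed=42, labeled=False,
                                             noise_sigma=0.2)
        pep_layer = doc.peptide_quant_layers[0]
        prot_layer = aggregate_proteins(doc, pep_layer)
        name_of = {a.id: a.name for a in doc.assays}
        for i, assay_ref in enumerate(pep_layer.assay_refs):
            total_area = sum(
                (r.area or 0.0) for r in rows
                if r.replicate_name == name_of[assay_ref]
            )
            pep_total = sum(v[i] for v in pep_layer.rows.values())
            prot_total = sum(v[i] for v in prot_layer.rows.values())
            assert pep_total == pytest.approx(total_area, rel=1e-12)
            assert prot_total == pytest.approx(total_area, rel=1e-12)


def test_permutation_invariance_of_aggregation():
    result, rows, doc = make_experiment(seed=43, labeled=True, noise_sigma=0.3)
    baseline = {
        (pep.sequence, pep.charge): dict(
            zip(doc.peptide_quant_layers[0].assay_refs,
                doc.peptide_quant_layers[0].rows[pep.id])
        )
        for pep in doc.peptides
    }
    name_of = {a.id: a.name for a in doc.assays}

    shuffled = list(rows)
    random.Random(7).shuffle(shuffled)
    doc2 = build_document(shuffled)
    name_of2 = {a.id: a.name for a in doc2.assays}
    layer2 = doc2.peptide_quant_layers[0]
    for pep in doc2.peptides:
        expected = baseline[(pep.sequence, pep.charge)]
        expected_by_name = {
            name_of[k]: v for k, v in expected.items()
        }
        for assay_ref, value in zip(layer2.assay_refs, layer2.rows[pep.id]):
            assert value == pytest.approx(
                expected_by_name[name_of2[assay_ref]], rel=1e-12, abs=0
            )
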