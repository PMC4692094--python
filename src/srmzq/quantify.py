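"""Transition -> peptide -> protein aggregation and light/heavy ratios.

SRM software reduces the per-transition XIC areas of a peptide to one
peptide-level value per assay by a sum, mean or weighted mean, and may
aggregate peptide values further to protein level.  In a labeled design
each replicate contributes a light and a heavy assay; the peptide ratio is
the quotient of the aggregated light and heavy values (sum first, then
divide).  A zero denominator yields NaN — the missing-value marker that
keeps mzQuantML matrices rectangular — plus a WARNING finding on the layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from . import cv
from .model import (
    Assay,
    AssayQuantLayer,
    Finding,
    Label,
    LabelMode,
    ObjectLevel,
    RatioDefinition,
    RatioQuantLayer,
    Severity,
    SrmDocument,
    param,
)


class PeptideMethod(str, Enum):
    SUM = "SUM"
    MEAN = "MEAN"
    WEIGHTED_MEAN = "WEIGHTED_MEAN"


class ProteinMethod(str, Enum):
    SUM = "SUM"
    MEAN = "MEAN"


_PEPTIDE_DATATYPE = {
    PeptideMethod.SUM: cv.SUMMED_XIC_AREA,
    PeptideMethod.MEAN: cv.MEAN_XIC_AREA,
    PeptideMethod.WEIGHTED_MEAN: cv.WEIGHTED_MEAN_XIC_AREA,
}

_PROTEIN_DATATYPE = {
    ProteinMethod.SUM: cv.SUMMED_PEPTIDE_VALUE,
    ProteinMethod.MEAN: cv.MEAN_PEPTIDE_VALUE,
}


@dataclass
class AggregationSpec:
    """How transition values roll up.  Defaults are the converter's stated
    behaviour: peptide = sum of XIC areas, protein = sum of peptide values.
    ``weight_column`` names the CV term whose cells weight a WEIGHTED_MEAN
    and must be set for that method only (it defaults to XIC area there)."""

    peptide_method: PeptideMethod = PeptideMethod.SUM
    protein_method: ProteinMethod = ProteinMethod.SUM
    weight_column: Optional[str] = None

    def __post_init__(self) -> None:
        if self.peptide_method is PeptideMethod.WEIGHTED_MEAN:
            if self.weight_column is None:
                self.weight_column = cv.XIC_AREA
        elif self.weight_column is not None:
            raise ValueError("weight_column is only meaningful for WEIGHTED_MEAN")


def feature_values(doc: SrmDocument, term_name: str) -> dict[str, float]:
    """Per-feature cells of the quant-layer column typed ``term_name``."""
    out: dict[str, float] = {}
    for fl in doc.feature_lists:
        for layer in fl.quant_layers:
            idx = layer.column_index_of(term_name)
            if idx is None:
                continue
            for ref, values in layer.rows.items():
                out[ref] = values[idx]
    return out


def aggregate_peptides(doc: SrmDocument, spec: AggregationSpec | None = None) -> AssayQuantLayer:
    """Peptide-level AssayQuantLayer: for each peptide and assay, the
    aggregation method applied to the XIC areas of that peptide's features
    measured in that assay.  A peptide with no feature in an assay gets 0.
    The layer's datatype CV term records the method."""
    spec = spec or AggregationSpec()
    areas = feature_values(doc, cv.XIC_AREA)
    if not areas and any(fl.features for fl in doc.feature_lists):
        raise ValueError("document has features but no XIC-area quant column")
    weights = (
        feature_values(doc, spec.weight_column)
        if spec.peptide_method is PeptideMethod.WEIGHTED_MEAN
        else {}
    )

    layer = AssayQuantLayer(
        id=doc.next_id("aql"),
        datatype=param(_PEPTIDE_DATATYPE[spec.peptide_method]),
        object_level=ObjectLevel.PEPTIDE,
        assay_refs=[a.id for a in doc.assays],
    )
    for pep in doc.peptides:
        row: list[float] = []
        for assay in doc.assays:
            refs = [
                ref
                for (assay_ref, _label), frefs in pep.evidence.items()
                if assay_ref == assay.id
                for ref in frefs
            ]
            xs = [areas.get(r, 0.0) for r in refs]
            if not xs:
                row.append(0.0)
            elif spec.peptide_method is PeptideMethod.SUM:
                row.append(sum(xs))
            elif spec.peptide_method is PeptideMethod.MEAN:
                row.append(sum(xs) / len(xs))
            else:
                ws = [weights.get(r, 0.0) for r in refs]
                total = sum(ws)
                if total == 0:
                    row.append(0.0)
                    layer.findings.append(
                        Finding(
                            "Q1",
                            Severity.WARNING,
                            f"AssayQuantLayer/{layer.id}/{pep.id}/{assay.id}",
                            f"all weights zero for peptide {pep.id} in assay "
                            f"{assay.id}; value set to 0",
                        )
                    )
                else:
                    row.append(sum(w * x for w, x in zip(ws, xs)) / total)
        layer.add_row(pep.id, row)
    return layer


def _replicate_of(assay: Assay) -> Optional[str]:
    for label in Label:
        suffix = f"_{label.value}"
        if assay.name.endswith(suffix):
            return assay.name[: -len(suffix)]
    return None


def compute_peptide_ratios(
    doc: SrmDocument, layer: AssayQuantLayer, flip: bool = False
) -> tuple[list[RatioDefinition], RatioQuantLayer]:
    """Per-replicate light/heavy ratio definitions plus the peptide
    RatioQuantLayer computed from a peptide-level assay layer.

    Labeled documents only: a label-free file carries no RatioList.  Assay
    channels of a replicate are paired by the ``<replicate>_<light|heavy>``
    naming convention the converter uses.  ``flip`` makes the ratio
    heavy/light instead of the default light/heavy.
    """
    if doc.label_mode is not LabelMode.MS1_LABEL_BASED:
        raise ValueError("label-free files carry no RatioList")

    pairs: dict[str, dict[Label, Assay]] = {}
    order: list[str] = []
    for assay in doc.assays:
        rep = _replicate_of(assay)
        if rep is None:
            raise ValueError(
                f"assay {assay.id} ({assay.name!r}) does not follow the "
                "<replicate>_<light|heavy> naming convention"
            )
        if rep not in pairs:
            pairs[rep] = {}
            order.append(rep)
        pairs[rep][assay.label] = assay

    definitions: list[RatioDefinition] = []
    for rep in order:
        channels = pairs[rep]
        if Label.LIGHT not in channels or Label.HEAVY not in channels:
            raise ValueError(f"replicate {rep!r} lacks a light or heavy assay")
        num, den = channels[Label.LIGHT], channels[Label.HEAVY]
        if flip:
            num, den = den, num
        definitions.append(
            RatioDefinition(
                id=doc.next_id("rat"),
                numerator_ref=num.id,
                denominator_ref=den.id,
            )
        )

    rql = RatioQuantLayer(
        id=doc.next_id("rql"),
        datatype=param(cv.RATIO_LIGHT_HEAVY),
        ratio_refs=[d.id for d in definitions],
    )
    for pep_id in layer.rows:
        values: list[float] = []
        for d in definitions:
            num = layer.value(pep_id, d.numerator_ref)
            den = layer.value(pep_id, d.denominator_ref)
            if den == 0:
                values.append(float("nan"))
                rql.findings.append(
                    Finding(
                        "Q2",
                        Severity.WARNING,
                        f"RatioQuantLayer/{rql.id}/{pep_id}/{d.id}",
                        f"denominator is 0 for peptide {pep_id}, ratio {d.id}; "
                        "recorded as NaN",
                    )
                )
            else:
                values.append(num / den)
        rql.add_row(pep_id, values)
    return definitions, rql


def aggregate_proteins(
    doc: SrmDocument, peptide_layer: AssayQuantLayer, spec: AggregationSpec | None = None
) -> AssayQuantLayer:
    """Protein-level AssayQuantLayer from a peptide layer, proteins in
    first-appearance order.  A protein with no quantified peptides is
    excluded from the matrix and noted as a WARNING on the layer."""
    spec = spec or AggregationSpec()
    layer = AssayQuantLayer(
        id=doc.next_id("pql"),
        datatype=param(_PROTEIN_DATATYPE[spec.protein_method]),
        object_level=ObjectLevel.PROTEIN,
        assay_refs=list(peptide_layer.assay_refs),
    )
    for prot in doc.proteins:
        rows = [peptide_layer.rows[r] for r in prot.peptide_refs if r in peptide_layer.rows]
        if not rows:
            layer.findings.append(
                Finding(
                    "Q3",
                    Severity.WARNING,
                    f"ProteinList/{prot.id}",
                    f"protein {prot.id} ({prot.accession}) has no quantified "
                    "peptides; excluded from the layer",
                )
            )
            continue
        sums = [sum(col) for col in zip(*rows)]
        if spec.protein_method is ProteinMethod.MEAN:
            sums = [s / len(rows) for s in sums]
        layer.add_row(prot.id, sums)
    return layer
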