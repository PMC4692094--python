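"""Skyline-style SRM report CSV -> SrmDocument conversion.

Skyline exports a transition report with one row per transition per
replicate.  The accepted column dialect (15 fields) is:

    ProteinName, PeptideModifiedSequence, PrecursorMz, PrecursorCharge,
    ProductMz, ProductCharge, FragmentIon, IsotopeLabelType, ReplicateName,
    FileName, RetentionTime, Area, Background, Height, Fwhm

Header matching is order- and case-insensitive after removing spaces, so
"Peptide Modified Sequence" and "peptidemodifiedsequence" both work.
Blank numeric cells and the literal "#N/A" are missing values; rows with a
missing Area still define a feature and quantify as 0.

Conversion rules: one raw-files group and one assay per distinct
(replicate, isotope label) pair; one Feature per transition instance with
the precursor data in attributes (precursor rt always "null" — Skyline's
reported retention time is the product-trace time and is mapped to the
"local retention time" product descriptor instead); a four-column
FeatureQuantLayer (XIC area, background, height, FWHM) per group; one
PeptideConsensus per (modified sequence, precursor charge) spanning both
label channels; peptide-level assay layer by summed XIC area; a RatioList
and light/heavy RatioQuantLayer only for labeled input.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO, Union

from . import __version__, cv
from .model import (
    Label,
    LabelMode,
    FeatureQuantLayer,
    QuantColumn,
    SrmDocument,
    make_transition_feature,
    new_document,
    param,
)
from .mzq_io import modification_descriptor
from .quantify import AggregationSpec, aggregate_peptides, compute_peptide_ratios


class ReportError(ValueError):
    """A Skyline report that cannot be converted (bad header, bad cell,
    duplicate transition, empty input)."""

#: normalized header name -> ReportRow field
COLUMNS = {
    "proteinname": "protein_name",
    "peptidemodifiedsequence": "peptide_modified_sequence",
    "precursormz": "precursor_mz",
    "precursorcharge": "precursor_charge",
    "productmz": "product_mz",
    "productcharge": "product_charge",
    "fragmention": "fragment_ion",
    "isotopelabeltype": "isotope_label_type",
    "replicatename": "replicate_name",
    "filename": "file_name",
    "retentiontime": "retention_time",
    "area": "area",
    "background": "background",
    "height": "height",
    "fwhm": "fwhm",
}

_FLOAT_FIELDS = ("retention_time", "area", "background", "height", "fwhm")
_MISSING = {"", "#N/A", "#N/A!", "NA"}


@dataclass
class ReportRow:
    """One transition measurement in one replicate, as reported by Skyline."""

    protein_name: str
    peptide_modified_sequence: str
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    product_charge: int
    fragment_ion: str
    isotope_label_type: str
    replicate_name: str
    file_name: str
    retention_time: Optional[float] = None
    area: Optional[float] = None
    background: Optional[float] = None
    height: Optional[float] = None
    fwhm: Optional[float] = None

    def __post_init__(self) -> None:
        self.isotope_label_type = self.isotope_label_type.lower()
        if self.isotope_label_type not in ("light", "heavy"):
            raise ValueError(
                f"IsotopeLabelType must be 'light' or 'heavy', "
                f"got {self.isotope_label_type!r}"
            )
        if self.precursor_charge < 1 or self.product_charge < 1:
            raise ValueError("charges must be >= 1")
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be > 0")

    @property
    def label(self) -> Label:
        return Label(self.isotope_label_type)


def _normalize(name: str) -> str:
    return name.replace(" ", "").lower()


def parse_report(source: Union[str, TextIO]) -> list[ReportRow]:
    """Parse a Skyline transition report into ReportRows.

    Raises :class:`srmzq.model.ReportError` when required header columns
    are missing (listing them) or a numeric cell cannot be parsed (naming
    the row number and column).
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    reader = csv.reader(stream)
    try:
        header = next(reader)
    except StopIteration:
        raise ReportError("empty report: no header row") from None

    positions: dict[str, int] = {}
    for i, name in enumerate(header):
        key = _normalize(name)
        if key in COLUMNS:
            positions[COLUMNS[key]] = i
    missing = [f for f in COLUMNS.values() if f not in positions]
    if missing:
        raise ReportError(f"missing required report columns: {', '.join(missing)}")

    rows: list[ReportRow] = []
    for lineno, record in enumerate(reader, start=2):
        if not record or all(cell.strip() == "" for cell in record):
            continue
        kwargs: dict = {}
        for fld, pos in positions.items():
            cell = record[pos].strip() if pos < len(record) else ""
            if fld in _FLOAT_FIELDS:
                if cell in _MISSING:
                    kwargs[fld] = None
                else:
                    try:
                        kwargs[fld] = float(cell)
                    except ValueError:
                        raise ReportError(
                            f"row {lineno}, column {fld}: cannot parse "
                            f"{cell!r} as a number"
                        ) from None
            elif fld in ("precursor_charge", "product_charge"):
                try:
                    kwargs[fld] = int(cell)
                except ValueError:
                    raise ReportError(
                        f"row {lineno}, column {fld}: cannot parse "
                        f"{cell!r} as an integer"
                    ) from None
            elif fld in ("precursor_mz", "product_mz"):
                try:
                    kwargs[fld] = float(cell)
                except ValueError:
                    raise ReportError(
                        f"row {lineno}, column {fld}: cannot parse "
                        f"{cell!r} as a number"
                    ) from None
            else:
                kwargs[fld] = cell
        try:
            rows.append(ReportRow(**kwargs))
        except ValueError as exc:
            raise ReportError(f"row {lineno}: {exc}") from None
    return rows


def detect_label_mode(rows: Iterable[ReportRow]) -> LabelMode:
    """LABEL_FREE iff every row is 'light'; any 'heavy' row makes the file
    label-based (a label-free Skyline report always says 'light')."""
    rows = list(rows)
    if not rows:
        raise ReportError("cannot detect label mode of an empty report")
    if all(r.label is Label.LIGHT for r in rows):
        return LabelMode.LABEL_FREE
    return LabelMode.MS1_LABEL_BASED


_MODSEQ_RE = re.compile(r"([A-Z])((?:\[[^\]]*\])*)|(\[[^\]]*\])")


def split_modified_sequence(modseq: str) -> tuple[str, str]:
    """Split a Skyline modified sequence such as ``PEPT[+80]IDER`` into the
    bare sequence and the canonical modification descriptor
    (sorted ``position:name`` pairs; positions are 1-based, 0 = N-terminal
    modification written before the first residue)."""
    sequence: list[str] = []
    pairs: list[tuple[int, str]] = []
    pos = 0
    i = 0
    while i < len(modseq):
        ch = modseq[i]
        if ch == "[":
            end = modseq.find("]", i)
            if end < 0:
                raise ReportError(f"unbalanced '[' in modified sequence {modseq!r}")
            pairs.append((pos, modseq[i + 1 : end]))
            i = end + 1
        else:
            sequence.append(ch.upper())
            pos += 1
            i += 1
    return "".join(sequence), modification_descriptor(pairs)


def build_document(
    rows: list[ReportRow],
    spec: AggregationSpec | None = None,
    flip_ratio: bool = False,
    label_mode_override: LabelMode | None = None,
) -> SrmDocument:
    """Convert parsed report rows into a complete, valid SrmDocument.

    Raises :class:`srmzq.model.ReportError` on an empty input or on
    duplicate transition instances (same replicate, peptide, precursor
    charge, fragment ion, product charge and label — an ambiguous feature).
    """
    if not rows:
        raise ReportError("cannot build a document from an empty report")
    spec = spec or AggregationSpec()
    mode = label_mode_override or detect_label_mode(rows)
    doc = new_document(mode)

    sw = doc.add_software("srmzq", __version__)

    # assays: one raw-files group + assay per (replicate, label), input order
    assay_ids: dict[tuple[str, Label], str] = {}
    group_ids: dict[tuple[str, Label], str] = {}
    for row in rows:
        key = (row.replicate_name, row.label)
        if key in assay_ids:
            continue
        group = doc.add_raw_file_group(row.file_name)
        group_ids[key] = group.id
        name = (
            row.replicate_name
            if mode is LabelMode.LABEL_FREE
            else f"{row.replicate_name}_{row.label.value}"
        )
        assay_ids[key] = doc.add_assay(name, group.id, row.label).id

    # features: one per transition instance, grouped by (replicate, label)
    feature_lists = {
        key: doc.add_feature_list(group_id) for key, group_id in group_ids.items()
    }
    seen: set[tuple] = set()
    measurements: dict[str, list[float]] = {}
    feature_of_row: list[str] = []
    for row in rows:
        tkey = (
            row.replicate_name,
            row.peptide_modified_sequence,
            row.precursor_charge,
            row.fragment_ion,
            row.product_charge,
            row.label,
        )
        if tkey in seen:
            raise ReportError(
                "duplicate transition instance (replicate="
                f"{row.replicate_name!r}, peptide="
                f"{row.peptide_modified_sequence!r}, charge="
                f"{row.precursor_charge}, fragment={row.fragment_ion!r}, "
                f"label={row.label.value}): ambiguous feature"
            )
        seen.add(tkey)
        ft = make_transition_feature(
            feature_id=doc.next_id("ft"),
            precursor_mz=row.precursor_mz,
            precursor_charge=row.precursor_charge,
            product_mz=row.product_mz,
            product_charge=row.product_charge,
            local_rt=row.retention_time,
            precursor_rt=None,
        )
        doc.add_feature(feature_lists[(row.replicate_name, row.label)], ft)
        measurements[ft.id] = [
            row.area or 0.0,
            row.background or 0.0,
            row.height or 0.0,
            row.fwhm or 0.0,
        ]
        feature_of_row.append(ft.id)

    # one four-column quant layer per raw-files group, fixed column order
    for fl in doc.feature_lists:
        layer = FeatureQuantLayer(
            id=doc.next_id("fql"),
            columns=[
                QuantColumn(0, param(cv.XIC_AREA)),
                QuantColumn(1, param(cv.XIC_BACKGROUND)),
                QuantColumn(2, param(cv.XIC_HEIGHT)),
                QuantColumn(3, param(cv.FWHM)),
            ],
        )
        for ft in fl.features:
            layer.add_row(ft.id, measurements[ft.id])
        fl.quant_layers.append(layer)

    # peptides: one consensus per (modified sequence, precursor charge)
    pep_ids: dict[tuple[str, int], str] = {}
    pep_by_id = {}
    for row, ft_id in zip(rows, feature_of_row):
        pkey = (row.peptide_modified_sequence, row.precursor_charge)
        if pkey not in pep_ids:
            sequence, mods = split_modified_sequence(row.peptide_modified_sequence)
            pep = doc.add_peptide(sequence, mods, row.precursor_charge)
            pep_ids[pkey] = pep.id
            pep_by_id[pep.id] = pep
        pep = pep_by_id[pep_ids[pkey]]
        pep.add_evidence(assay_ids[(row.replicate_name, row.label)], row.label, ft_id)

    # proteins in first-appearance order, with their peptides
    prot_of_name: dict[str, object] = {}
    for row in rows:
        prot = prot_of_name.get(row.protein_name)
        if prot is None:
            prot = doc.add_protein(row.protein_name)
            prot_of_name[row.protein_name] = prot
        pep_id = pep_ids[(row.peptide_modified_sequence, row.precursor_charge)]
        if pep_id not in prot.peptide_refs:
            prot.peptide_refs.append(pep_id)

    peptide_layer = aggregate_peptides(doc, spec)
    doc.peptide_quant_layers.append(peptide_layer)

    if mode is LabelMode.MS1_LABEL_BASED:
        defs, rql = compute_peptide_ratios(doc, peptide_layer, flip=flip_ratio)
        doc.ratio_definitions = defs
        doc.ratio_quant_layer = rql

    doc.add_processing_step(
        sw.id,
        [
            param("Skyline transition report conversion"),
            param("peptide aggregation method", spec.peptide_method.value),
            param("ratio orientation",
                  ("heavy/light" if flip_ratio else "light/heavy"))
            if mode is LabelMode.MS1_LABEL_BASED
            else param("ratio computation", "none (label-free)"),
        ],
    )
    return doc
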