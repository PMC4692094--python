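"""mzQuantML 1.0.1 XML reader/writer for the SRM dialect.

The writer is canonical: the same document always yields the same bytes
(fixed element order, fixed attribute order, fixed number rendering), so
converted files can be compared byte-for-byte.  The reader accepts any
well-formed mzQuantML file, keeps unknown top-level elements in an opaque
extras store for re-emission, and enforces the structural rules that must
hold before semantics can be checked (compulsory AnalysisSummary,
rectangular data matrices, unique feature ids).

Schema element order: CvList, AnalysisSummary, InputFiles, SoftwareList,
DataProcessingList, AssayList, RatioList?, ProteinList?,
PeptideConsensusList, FeatureList*.
"""

from __future__ import annotations

import copy
import math
import re
from dataclasses import dataclass
from typing import Optional

from lxml import etree

from . import cv
from .model import (
    AnalysisSummary,
    Assay,
    AssayQuantLayer,
    CvParam,
    DataProcessingStep,
    FeatureList,
    FeatureQuantLayer,
    Label,
    LabelMode,
    ObjectLevel,
    PeptideConsensus,
    ProteinEntry,
    QuantColumn,
    RatioDefinition,
    RatioQuantLayer,
    RawFile,
    RawFilesGroup,
    Severity,
    Software,
    SrmDocument,
    TransitionFeature,
    resolve_references,
)

NAMESPACE = "http://psidev.info/psi/pi/mzQuantML/1.0"
_NS = f"{{{NAMESPACE}}}"


class MzqError(Exception):
    """Base class for mzQuantML I/O failures."""


class MzqParseError(MzqError):
    """The input is not well-formed XML."""


class StructuralError(MzqError):
    """Well-formed XML that violates the dialect's structural contract."""


class UnresolvedReferencesError(MzqError):
    """Serialization refused: the document's reference graph has danglers."""

    def __init__(self, danglers: list[str]):
        self.danglers = danglers
        super().__init__(
            "document has unresolved references; refusing to serialize: "
            + "; ".join(danglers)
        )


class SchemaValidationError(MzqError):
    """Optional XSD validation against an official schema failed."""


@dataclass
class SerializationOptions:
    pretty_print: bool = True
    schema_location: Optional[str] = None


def format_number(x: float) -> str:
    """Canonical decimal rendering: '.' separator, up to 6 fractional
    digits, trailing zeros stripped, never exponent notation; NaN -> "NaN"
    (the missing-value marker in rectangular matrices)."""
    if math.isnan(x):
        return "NaN"
    if math.isinf(x):
        raise ValueError("infinite values cannot be serialized")
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    if s in ("", "-0"):
        return "0"
    return s


def parse_number(text: str) -> float:
    if text == "NaN":
        return float("nan")
    return float(text)


# ---------------------------------------------------------------------------
# writing


def _param_el(parent: etree._Element, p: CvParam) -> None:
    if p.accession is not None:
        el = etree.SubElement(parent, _NS + "cvParam")
        el.set("cvRef", "PSI-MS")
        el.set("accession", p.accession)
    else:
        el = etree.SubElement(parent, _NS + "userParam")
    el.set("name", p.name)
    if p.value is not None:
        el.set("value", p.value)
    if p.unit_name is not None:
        el.set("unitName", p.unit_name)


def _datatype_el(parent: etree._Element, p: CvParam) -> None:
    dt = etree.SubElement(parent, _NS + "DataType")
    _param_el(dt, p)


def _assay_layer_el(parent: etree._Element, layer: AssayQuantLayer) -> None:
    el = etree.SubElement(parent, _NS + "AssayQuantLayer")
    el.set("id", layer.id)
    _datatype_el(el, layer.datatype)
    ci = etree.SubElement(el, _NS + "ColumnIndex")
    ci.text = " ".join(layer.assay_refs)
    _matrix_el(el, layer.rows)


def _matrix_el(parent: etree._Element, rows: dict[str, list[float]]) -> None:
    dm = etree.SubElement(parent, _NS + "DataMatrix")
    for ref, values in rows.items():
        row = etree.SubElement(dm, _NS + "Row")
        row.set("object_ref", ref)
        row.text = " ".join(format_number(v) for v in values)


def _modification_pairs(descriptor: str) -> list[tuple[int, str]]:
    if not descriptor:
        return []
    pairs = []
    for chunk in descriptor.split(";"):
        pos, _, name = chunk.partition(":")
        pairs.append((int(pos), name))
    return pairs


def modification_descriptor(pairs: list[tuple[int, str]]) -> str:
    """Canonical modification string: sorted ``pos:name`` pairs joined by ';'."""
    return ";".join(f"{pos}:{name}" for pos, name in sorted(pairs))


def write_mzq(doc: SrmDocument, options: SerializationOptions | None = None) -> bytes:
    """Serialize ``doc`` to mzQuantML 1.0.1 bytes.

    Refuses documents with dangling cross-references (the resulting file
    could never validate).  Output is deterministic.
    """
    options = options or SerializationOptions()
    danglers = resolve_references(doc)
    if danglers:
        raise UnresolvedReferencesError([f.message for f in danglers])

    root = etree.Element(_NS + "MzQuantML", nsmap={None: NAMESPACE})
    root.set("id", doc.id)
    root.set("version", "1.0.1")

    cvlist = etree.SubElement(root, _NS + "CvList")
    cv_el = etree.SubElement(cvlist, _NS + "Cv")
    cv_el.set("id", "PSI-MS")
    cv_el.set("fullName", "Proteomics Standards Initiative Mass Spectrometry Vocabularies")
    cv_el.set("uri", "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")

    summary = etree.SubElement(root, _NS + "AnalysisSummary")
    for p in doc.analysis_summary.technique_terms:
        _param_el(summary, p)

    input_files = etree.SubElement(root, _NS + "InputFiles")
    for group in doc.raw_file_groups:
        g = etree.SubElement(input_files, _NS + "RawFilesGroup")
        g.set("id", group.id)
        for rf in group.raw_files:
            r = etree.SubElement(g, _NS + "RawFile")
            r.set("id", rf.id)
            r.set("location", rf.location)

    sw_list = etree.SubElement(root, _NS + "SoftwareList")
    for sw in doc.software:
        s = etree.SubElement(sw_list, _NS + "Software")
        s.set("id", sw.id)
        s.set("version", sw.version)
        _param_el(s, CvParam(name=sw.name, accession=cv.accession_for(sw.name)))

    dp_list = etree.SubElement(root, _NS + "DataProcessingList")
    for step in doc.data_processing:
        d = etree.SubElement(dp_list, _NS + "DataProcessing")
        d.set("id", step.id)
        d.set("software_ref", step.software_ref)
        d.set("order", str(step.order))
        method = etree.SubElement(d, _NS + "ProcessingMethod")
        method.set("order", "1")
        for p in step.params:
            _param_el(method, p)

    assay_list = etree.SubElement(root, _NS + "AssayList")
    assay_list.set("id", "AssayList_1")
    for assay in doc.assays:
        a = etree.SubElement(assay_list, _NS + "Assay")
        a.set("id", assay.id)
        a.set("name", assay.name)
        a.set("rawFilesGroup_ref", assay.raw_file_ref)
        label = etree.SubElement(a, _NS + "Label")
        mod = etree.SubElement(label, _NS + "Modification")
        _param_el(mod, assay.label_param)

    if doc.ratio_definitions:
        ratio_list = etree.SubElement(root, _NS + "RatioList")
        for ratio in doc.ratio_definitions:
            r = etree.SubElement(ratio_list, _NS + "Ratio")
            r.set("id", ratio.id)
            r.set("numerator_ref", ratio.numerator_ref)
            r.set("denominator_ref", ratio.denominator_ref)

    if doc.proteins or doc.protein_quant_layers:
        prot_list = etree.SubElement(root, _NS + "ProteinList")
        prot_list.set("id", "ProteinList_1")
        for prot in doc.proteins:
            p = etree.SubElement(prot_list, _NS + "Protein")
            p.set("id", prot.id)
            p.set("accession", prot.accession)
            if prot.peptide_refs:
                refs = etree.SubElement(p, _NS + "PeptideConsensus_refs")
                refs.text = " ".join(prot.peptide_refs)
        for layer in doc.protein_quant_layers:
            _assay_layer_el(prot_list, layer)

    pep_list = etree.SubElement(root, _NS + "PeptideConsensusList")
    pep_list.set("id", "PeptideConsensusList_1")
    pep_list.set("finalResult", "true")
    for pep in doc.peptides:
        p = etree.SubElement(pep_list, _NS + "PeptideConsensus")
        p.set("id", pep.id)
        p.set("charge", str(pep.charge))
        seq = etree.SubElement(p, _NS + "PeptideSequence")
        seq.text = pep.sequence
        for pos, name in _modification_pairs(pep.modifications):
            m = etree.SubElement(p, _NS + "Modification")
            m.set("location", str(pos))
            _param_el(m, CvParam(name=name))
        for (assay_ref, _label), feature_refs in pep.evidence.items():
            for fref in feature_refs:
                ev = etree.SubElement(p, _NS + "EvidenceRef")
                ev.set("feature_ref", fref)
                ev.set("assay_refs", assay_ref)
    for layer in doc.peptide_quant_layers:
        _assay_layer_el(pep_list, layer)
    if doc.ratio_quant_layer is not None:
        rql = doc.ratio_quant_layer
        el = etree.SubElement(pep_list, _NS + "RatioQuantLayer")
        el.set("id", rql.id)
        _datatype_el(el, rql.datatype)
        ci = etree.SubElement(el, _NS + "ColumnIndex")
        ci.text = " ".join(rql.ratio_refs)
        _matrix_el(el, rql.rows)

    for fl in doc.feature_lists:
        f = etree.SubElement(root, _NS + "FeatureList")
        f.set("id", fl.id)
        f.set("rawFilesGroup_ref", fl.raw_files_group_ref)
        for ft in fl.features:
            fe = etree.SubElement(f, _NS + "Feature")
            fe.set("id", ft.id)
            # precursor RT unknown -> literal "null", the schema's convention
            fe.set("rt", "null" if ft.precursor_rt is None else format_number(ft.precursor_rt))
            fe.set("mz", format_number(ft.precursor_mz))
            fe.set("charge", str(ft.precursor_charge))
            for p in ft.product_params:
                _param_el(fe, p)
        for layer in fl.quant_layers:
            le = etree.SubElement(f, _NS + "FeatureQuantLayer")
            le.set("id", layer.id)
            cd = etree.SubElement(le, _NS + "ColumnDefinition")
            for col in layer.columns:
                c = etree.SubElement(cd, _NS + "Column")
                c.set("index", str(col.column_index))
                _datatype_el(c, col.datatype)
            _matrix_el(le, layer.rows)

    for extra in doc.extras:
        root.append(copy.deepcopy(extra))

    data = etree.tostring(
        root,
        xml_declaration=True,
        encoding="UTF-8",
        pretty_print=options.pretty_print,
    )
    if options.schema_location:
        validate_against_schema(data, options.schema_location)
    return data


def validate_against_schema(data: bytes, schema_path: str) -> None:
    """Validate serialized bytes against an official XSD (optional check)."""
    schema = etree.XMLSchema(etree.parse(schema_path))
    document = etree.fromstring(data)
    if not schema.validate(document):
        raise SchemaValidationError(str(schema.error_log))


# ---------------------------------------------------------------------------
# reading


def _strip(tag: str) -> str:
    return tag.split("}", 1)[1] if "}" in tag else tag


def _read_param(el: etree._Element) -> CvParam:
    return CvParam(
        name=el.get("name", ""),
        accession=el.get("accession") if _strip(el.tag) == "cvParam" else None,
        value=el.get("value"),
        unit_name=el.get("unitName"),
    )


def _read_params(parent: etree._Element) -> list[CvParam]:
    return [
        _read_param(el)
        for el in parent
        if _strip(el.tag) in ("cvParam", "userParam")
    ]


def _child(parent, tag):
    for el in parent:
        if _strip(el.tag) == tag:
            return el
    return None


def _children(parent, tag):
    return [el for el in parent if _strip(el.tag) == tag]


def _read_datatype(parent: etree._Element, where: str) -> CvParam:
    dt = _child(parent, "DataType")
    if dt is None or len(dt) == 0:
        raise StructuralError(f"{where}: missing DataType")
    return _read_param(dt[0])


def _read_matrix(parent: etree._Element, where: str, width: int) -> dict[str, list[float]]:
    rows: dict[str, list[float]] = {}
    dm = _child(parent, "DataMatrix")
    if dm is None:
        return rows
    for row in _children(dm, "Row"):
        ref = row.get("object_ref", "")
        values = [parse_number(v) for v in (row.text or "").split()]
        if len(values) != width:
            raise StructuralError(
                f"{where}, row {ref}: {len(values)} values for {width} columns"
            )
        rows[ref] = values
    return rows


def _read_assay_layer(el: etree._Element, level: ObjectLevel) -> AssayQuantLayer:
    layer_id = el.get("id", "")
    where = f"AssayQuantLayer {layer_id}"
    datatype = _read_datatype(el, where)
    ci = _child(el, "ColumnIndex")
    assay_refs = (ci.text or "").split() if ci is not None else []
    layer = AssayQuantLayer(
        id=layer_id, datatype=datatype, object_level=level, assay_refs=assay_refs
    )
    layer.rows = _read_matrix(el, where, len(assay_refs))
    return layer


_ID_RE = re.compile(r"^([A-Za-z]+)_(\d+)$")


def _restore_counters(doc: SrmDocument) -> None:
    ids: list[str] = [doc.id]
    for g in doc.raw_file_groups:
        ids.append(g.id)
        ids.extend(rf.id for rf in g.raw_files)
    ids.extend(s.id for s in doc.software)
    ids.extend(s.id for s in doc.data_processing)
    ids.extend(a.id for a in doc.assays)
    ids.extend(r.id for r in doc.ratio_definitions)
    ids.extend(p.id for p in doc.proteins)
    ids.extend(l.id for l in doc.protein_quant_layers)
    ids.extend(p.id for p in doc.peptides)
    ids.extend(l.id for l in doc.peptide_quant_layers)
    if doc.ratio_quant_layer is not None:
        ids.append(doc.ratio_quant_layer.id)
    for fl in doc.feature_lists:
        ids.append(fl.id)
        ids.extend(ft.id for ft in fl.features)
        ids.extend(l.id for l in fl.quant_layers)
    for i in ids:
        m = _ID_RE.match(i)
        if m:
            kind, n = m.group(1), int(m.group(2))
            doc._counters[kind] = max(doc._counters.get(kind, 0), n + 1)


_KNOWN_ROOT_TAGS = {
    "CvList",
    "AnalysisSummary",
    "InputFiles",
    "SoftwareList",
    "DataProcessingList",
    "AssayList",
    "RatioList",
    "ProteinList",
    "PeptideConsensusList",
    "FeatureList",
}


def read_mzq(data: bytes) -> SrmDocument:
    """Parse mzQuantML bytes into an :class:`SrmDocument`.

    Raises :class:`MzqParseError` on malformed XML (message carries the
    line number) and :class:`StructuralError` on dialect violations that
    make the document unusable (no AnalysisSummary, ragged matrix rows,
    duplicate feature ids).
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise MzqParseError(f"not well-formed XML: {exc}") from exc

    doc = SrmDocument()
    doc.id = root.get("id", "SRM_doc")

    summary_el = _child(root, "AnalysisSummary")
    if summary_el is None:
        raise StructuralError(
            "missing AnalysisSummary: it is a compulsory element in mzQuantML"
        )
    terms = _read_params(summary_el)
    summary = AnalysisSummary(technique_terms=terms)
    is_lf = summary.has_term(cv.LABEL_FREE_ANALYSIS)
    is_lb = summary.has_term(cv.MS1_LABEL_BASED_ANALYSIS)
    if is_lf != is_lb:
        summary.label_mode = LabelMode.LABEL_FREE if is_lf else LabelMode.MS1_LABEL_BASED
    doc.analysis_summary = summary

    input_files = _child(root, "InputFiles")
    if input_files is not None:
        for g in _children(input_files, "RawFilesGroup"):
            group = RawFilesGroup(id=g.get("id", ""))
            for rf in _children(g, "RawFile"):
                group.raw_files.append(
                    RawFile(id=rf.get("id", ""), location=rf.get("location", ""))
                )
            doc.raw_file_groups.append(group)

    sw_list = _child(root, "SoftwareList")
    if sw_list is not None:
        for s in _children(sw_list, "Software"):
            params = _read_params(s)
            name = params[0].name if params else "unknown"
            doc.software.append(
                Software(id=s.get("id", ""), name=name, version=s.get("version", ""))
            )

    dp_list = _child(root, "DataProcessingList")
    if dp_list is not None:
        for d in _children(dp_list, "DataProcessing"):
            method = _child(d, "ProcessingMethod")
            doc.data_processing.append(
                DataProcessingStep(
                    id=d.get("id", ""),
                    software_ref=d.get("software_ref", ""),
                    order=int(d.get("order", "1")),
                    params=_read_params(method) if method is not None else [],
                )
            )

    assay_list = _child(root, "AssayList")
    if assay_list is not None:
        for a in _children(assay_list, "Assay"):
            label_param = CvParam(name=cv.UNLABELED_SAMPLE,
                                  accession=cv.accession_for(cv.UNLABELED_SAMPLE))
            label_el = _child(a, "Label")
            if label_el is not None:
                mod = _child(label_el, "Modification")
                if mod is not None and len(mod):
                    label_param = _read_param(mod[0])
            label = (
                Label.LIGHT if label_param.is_term(cv.UNLABELED_SAMPLE) else Label.HEAVY
            )
            doc.assays.append(
                Assay(
                    id=a.get("id", ""),
                    name=a.get("name", ""),
                    raw_file_ref=a.get("rawFilesGroup_ref", ""),
                    label=label,
                    label_param=label_param,
                )
            )
    assay_labels = {a.id: a.label for a in doc.assays}

    ratio_list = _child(root, "RatioList")
    if ratio_list is not None:
        for r in _children(ratio_list, "Ratio"):
            doc.ratio_definitions.append(
                RatioDefinition(
                    id=r.get("id", ""),
                    numerator_ref=r.get("numerator_ref", ""),
                    denominator_ref=r.get("denominator_ref", ""),
                )
            )

    prot_list = _child(root, "ProteinList")
    if prot_list is not None:
        for p in _children(prot_list, "Protein"):
            prot = ProteinEntry(id=p.get("id", ""), accession=p.get("accession", ""))
            refs = _child(p, "PeptideConsensus_refs")
            if refs is not None and refs.text:
                prot.peptide_refs = refs.text.split()
            doc.proteins.append(prot)
        for layer_el in _children(prot_list, "AssayQuantLayer"):
            doc.protein_quant_layers.append(
                _read_assay_layer(layer_el, ObjectLevel.PROTEIN)
            )

    pep_list = _child(root, "PeptideConsensusList")
    if pep_list is not None:
        for p in _children(pep_list, "PeptideConsensus"):
            seq_el = _child(p, "PeptideSequence")
            pairs = []
            for m in _children(p, "Modification"):
                name = m[0].get("name", "") if len(m) else ""
                pairs.append((int(m.get("location", "0")), name))
            pep = PeptideConsensus(
                id=p.get("id", ""),
                sequence=(seq_el.text or "") if seq_el is not None else "",
                modifications=modification_descriptor(pairs),
                charge=int(p.get("charge", "1")),
            )
            for ev in _children(p, "EvidenceRef"):
                fref = ev.get("feature_ref", "")
                for assay_ref in (ev.get("assay_refs") or "").split():
                    label = assay_labels.get(assay_ref, Label.LIGHT)
                    pep.add_evidence(assay_ref, label, fref)
            doc.peptides.append(pep)
        for layer_el in _children(pep_list, "AssayQuantLayer"):
            doc.peptide_quant_layers.append(
                _read_assay_layer(layer_el, ObjectLevel.PEPTIDE)
            )
        rql_el = _child(pep_list, "RatioQuantLayer")
        if rql_el is not None:
            layer_id = rql_el.get("id", "")
            where = f"RatioQuantLayer {layer_id}"
            ci = _child(rql_el, "ColumnIndex")
            ratio_refs = (ci.text or "").split() if ci is not None else []
            rql = RatioQuantLayer(
                id=layer_id,
                datatype=_read_datatype(rql_el, where),
                ratio_refs=ratio_refs,
            )
            rql.rows = _read_matrix(rql_el, where, len(ratio_refs))
            doc.ratio_quant_layer = rql

    seen_features: set[str] = set()
    for f in _children(root, "FeatureList"):
        fl = FeatureList(
            id=f.get("id", ""), raw_files_group_ref=f.get("rawFilesGroup_ref", "")
        )
        for fe in _children(f, "Feature"):
            rt_attr = fe.get("rt", "null")
            ft = TransitionFeature(
                id=fe.get("id", ""),
                precursor_mz=parse_number(fe.get("mz", "0")),
                precursor_charge=int(fe.get("charge", "1")),
                precursor_rt=None if rt_attr == "null" else parse_number(rt_attr),
                product_params=_read_params(fe),
            )
            if ft.id in seen_features:
                raise StructuralError(f"duplicate feature id {ft.id}")
            seen_features.add(ft.id)
            fl.features.append(ft)
        for layer_el in _children(f, "FeatureQuantLayer"):
            layer_id = layer_el.get("id", "")
            where = f"FeatureQuantLayer {layer_id}"
            columns = []
            cd = _child(layer_el, "ColumnDefinition")
            if cd is not None:
                for c in _children(cd, "Column"):
                    columns.append(
                        QuantColumn(
                            column_index=int(c.get("index", "0")),
                            datatype=_read_datatype(c, where),
                        )
                    )
            layer = FeatureQuantLayer(id=layer_id, columns=columns)
            layer.rows = _read_matrix(layer_el, where, len(columns))
            fl.quant_layers.append(layer)
        doc.feature_lists.append(fl)

    for el in root:
        if _strip(el.tag) not in _KNOWN_ROOT_TAGS:
            doc.extras.append(el)

    _restore_counters(doc)
    return doc
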