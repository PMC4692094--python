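"""In-memory domain model for the SRM dialect of mzQuantML 1.0.1.

The unit of measurement in selected reaction monitoring (SRM) is the
*transition*: a precursor ion m/z selected in Q1 paired with a product ion
m/z selected in Q3, monitored over chromatographic time.  mzQuantML encodes
one quantified transition as a ``<Feature>`` whose attributes (rt, mz,
charge) describe the MS1 precursor and whose CV parameters ("local
retention time", "isolation window target m/z", "charge state") describe
the MS2 product.  Per-transition measurements (XIC area, background,
height, peak width) live in a multi-column FeatureQuantLayer; peptide- and
protein-level values live in single-datatype AssayQuantLayers; light/heavy
ratios live in a RatioQuantLayer keyed by assay-pair Ratio definitions.

Everything here is a plain dataclass; serialization is in
:mod:`srmzq.mzq_io`, semantics checking in :mod:`srmzq.validate`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterator, Optional

from . import cv


class LabelMode(str, Enum):
    """Experimental design: label-free or MS1 isotope-label-based SRM."""

    LABEL_FREE = "LABEL_FREE"
    MS1_LABEL_BASED = "MS1_LABEL_BASED"


class Label(str, Enum):
    """Isotope channel of an assay."""

    LIGHT = "light"
    HEAVY = "heavy"


class ObjectLevel(str, Enum):
    PEPTIDE = "PEPTIDE"
    PROTEIN = "PROTEIN"


class Severity(str, Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


_ACCESSION_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.-]*:\d+$")

#: ids a Finding may carry: validator rules R1..R10 plus the operational
#: warnings the quantification layer can attach (Q1 zero weights, Q2 zero
#: ratio denominator, Q3 protein without peptides).
KNOWN_FINDING_IDS = frozenset(
    {f"R{i}" for i in range(1, 11)} | {"Q1", "Q2", "Q3"}
)


@dataclass
class CvParam:
    """A controlled-vocabulary annotation: accession + name (+ value, unit).

    ``accession=None`` marks a name-only term of this dialect; it is
    serialized as a userParam.
    """

    name: str
    accession: Optional[str] = None
    value: Optional[str] = None
    unit_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("CvParam name must be non-empty")
        if self.accession is not None and not _ACCESSION_RE.match(self.accession):
            raise ValueError(
                f"CvParam accession {self.accession!r} does not match PREFIX:digits"
            )

    def is_term(self, term_name: str) -> bool:
        return cv.same_term(self.accession, self.name, term_name)


def param(name: str, value: Any = None, unit_name: str | None = None) -> CvParam:
    """Build a CvParam for a dialect term, filling the accession from the table."""
    return CvParam(
        name=name,
        accession=cv.accession_for(name),
        value=None if value is None else str(value),
        unit_name=unit_name,
    )


@dataclass
class AnalysisSummary:
    """Technique declaration: the compulsory element every reader checks first.

    For SRM files it must carry "SRM quantitation analysis" plus exactly one
    of the two design-mode terms; ``label_mode`` mirrors the mode term
    (None when the terms do not determine it).
    """

    technique_terms: list[CvParam] = field(default_factory=list)
    label_mode: Optional[LabelMode] = None

    def has_term(self, term_name: str) -> bool:
        return any(p.is_term(term_name) for p in self.technique_terms)


@dataclass
class RawFile:
    id: str
    location: str


@dataclass
class RawFilesGroup:
    id: str
    raw_files: list[RawFile] = field(default_factory=list)


@dataclass
class Software:
    id: str
    name: str
    version: str


@dataclass
class DataProcessingStep:
    """One step of the processing trace (software + parameters)."""

    id: str
    software_ref: str
    order: int
    params: list[CvParam] = field(default_factory=list)


@dataclass
class Assay:
    """One measured sample channel; in labeled SRM each isotope channel of a
    replicate is its own assay (so ratios can be assay-vs-assay)."""

    id: str
    name: str
    raw_file_ref: str
    label: Label
    label_param: CvParam = field(
        default_factory=lambda: param(cv.UNLABELED_SAMPLE)
    )


@dataclass
class TransitionFeature:
    """One quantified transition in one run.

    Precursor (MS1) data are attributes; product (MS2) data are CV params.
    An unknown precursor retention time is ``None`` (serialized "null"),
    never a sentinel number.
    """

    id: str
    precursor_mz: float
    precursor_charge: int
    precursor_rt: Optional[float] = None
    product_params: list[CvParam] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"feature {self.id}: precursor m/z must be > 0")
        if self.precursor_charge < 1:
            raise ValueError(f"feature {self.id}: precursor charge must be >= 1")

    def product_param(self, term_name: str) -> Optional[CvParam]:
        for p in self.product_params:
            if p.is_term(term_name):
                return p
        return None


def make_transition_feature(
    feature_id: str,
    precursor_mz: float,
    precursor_charge: int,
    product_mz: float,
    product_charge: int,
    local_rt: Optional[float] = None,
    precursor_rt: Optional[float] = None,
    extra_params: Optional[list[CvParam]] = None,
) -> TransitionFeature:
    """Construct a feature carrying the three required product descriptors."""
    if product_mz <= 0:
        raise ValueError(f"feature {feature_id}: product m/z must be > 0")
    if product_charge < 1:
        raise ValueError(f"feature {feature_id}: product charge must be >= 1")
    params = [
        param(cv.ISOLATION_TARGET_MZ, product_mz, unit_name="m/z"),
        param(cv.LOCAL_RT, local_rt, unit_name="minute"),
        param(cv.CHARGE_STATE, product_charge),
    ]
    if extra_params:
        params.extend(extra_params)
    return TransitionFeature(
        id=feature_id,
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        precursor_rt=precursor_rt,
        product_params=params,
    )


@dataclass
class QuantColumn:
    column_index: int
    datatype: CvParam


@dataclass
class FeatureQuantLayer:
    """Matrix of per-feature measurements; unlike assay/ratio layers it may
    define several column datatypes.  Row length must equal the column count
    (enforced at construction: the matrix-shape rule)."""

    id: str
    columns: list[QuantColumn] = field(default_factory=list)
    rows: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, col in enumerate(self.columns):
            if col.column_index != i:
                raise ValueError(
                    f"layer {self.id}: column indices must run 0..n-1 "
                    f"(got {col.column_index} at position {i})"
                )
        for ref, values in self.rows.items():
            self._check_row(ref, values)

    def _check_row(self, feature_ref: str, values: list[float]) -> None:
        if len(values) != len(self.columns):
            raise ValueError(
                f"layer {self.id}, row {feature_ref}: {len(values)} values "
                f"for {len(self.columns)} columns"
            )

    def add_row(self, feature_ref: str, values: list[float]) -> None:
        self._check_row(feature_ref, values)
        self.rows[feature_ref] = list(values)

    def column_index_of(self, term_name: str) -> Optional[int]:
        for col in self.columns:
            if col.datatype.is_term(term_name):
                return col.column_index
        return None


@dataclass
class AssayQuantLayer:
    """Single-datatype matrix: one row per peptide/protein, one column per
    assay (column order = ``assay_refs``)."""

    id: str
    datatype: CvParam
    object_level: ObjectLevel
    assay_refs: list[str] = field(default_factory=list)
    rows: dict[str, list[float]] = field(default_factory=dict)
    findings: list["Finding"] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        for ref, values in self.rows.items():
            self._check_row(ref, values)

    def _check_row(self, object_ref: str, values: list[float]) -> None:
        if len(values) != len(self.assay_refs):
            raise ValueError(
                f"layer {self.id}, row {object_ref}: {len(values)} values "
                f"for {len(self.assay_refs)} assays"
            )

    def add_row(self, object_ref: str, values: list[float]) -> None:
        self._check_row(object_ref, values)
        self.rows[object_ref] = list(values)

    def value(self, object_ref: str, assay_ref: str) -> float:
        return self.rows[object_ref][self.assay_refs.index(assay_ref)]


@dataclass
class RatioDefinition:
    """Numerator/denominator pair of assay refs (light over heavy by default)."""

    id: str
    numerator_ref: str
    denominator_ref: str


@dataclass
class RatioQuantLayer:
    """One row per peptide, one column per Ratio definition."""

    id: str
    datatype: CvParam
    ratio_refs: list[str] = field(default_factory=list)
    rows: dict[str, list[float]] = field(default_factory=dict)
    findings: list["Finding"] = field(default_factory=list, compare=False)

    def add_row(self, object_ref: str, values: list[float]) -> None:
        if len(values) != len(self.ratio_refs):
            raise ValueError(
                f"layer {self.id}, row {object_ref}: {len(values)} values "
                f"for {len(self.ratio_refs)} ratios"
            )
        self.rows[object_ref] = list(values)


_SEQUENCE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass
class PeptideConsensus:
    """A modified peptide at one precursor charge, with references to every
    feature (transition) that contributed evidence, keyed by (assay, label).

    One consensus spans both isotope channels of a labeled experiment.
    Identity = (sequence, modification descriptor, charge).
    """

    id: str
    sequence: str
    modifications: str  # canonical "pos:name;pos:name" descriptor, "" if none
    charge: int
    evidence: dict[tuple[str, Label], list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"peptide {self.id}: charge must be >= 1")
        if not _SEQUENCE_RE.match(self.sequence):
            raise ValueError(
                f"peptide {self.id}: sequence {self.sequence!r} is not an "
                "uppercase amino-acid string"
            )

    def add_evidence(self, assay_ref: str, label: Label, feature_ref: str) -> None:
        self.evidence.setdefault((assay_ref, label), []).append(feature_ref)

    def all_feature_refs(self) -> Iterator[str]:
        for refs in self.evidence.values():
            yield from refs


@dataclass
class ProteinEntry:
    id: str
    accession: str  # protein name as reported
    peptide_refs: list[str] = field(default_factory=list)


@dataclass
class FeatureList:
    """Features (and their quant layers) of one raw-files group."""

    id: str
    raw_files_group_ref: str
    features: list[TransitionFeature] = field(default_factory=list)
    quant_layers: list[FeatureQuantLayer] = field(default_factory=list)


@dataclass
class Finding:
    """One validator/quantifier result: rule id, severity, element path, message."""

    rule_id: str
    severity: Severity
    element_path: str
    message: str

    def __post_init__(self) -> None:
        if self.rule_id not in KNOWN_FINDING_IDS:
            raise ValueError(f"unknown finding id {self.rule_id!r}")


@dataclass
class SrmDocument:
    """A whole SRM mzQuantML file.

    Construction helpers (``add_*``) hand out deterministic
    ``<kind>_<ordinal>`` identifiers in insertion order so repeated
    conversion of the same input is byte-identical, and enforce feature-id
    uniqueness.  Cross-reference closure is checked by
    :func:`resolve_references`.
    """

    analysis_summary: AnalysisSummary = field(default_factory=AnalysisSummary)
    raw_file_groups: list[RawFilesGroup] = field(default_factory=list)
    software: list[Software] = field(default_factory=list)
    data_processing: list[DataProcessingStep] = field(default_factory=list)
    assays: list[Assay] = field(default_factory=list)
    ratio_definitions: list[RatioDefinition] = field(default_factory=list)
    proteins: list[ProteinEntry] = field(default_factory=list)
    protein_quant_layers: list[AssayQuantLayer] = field(default_factory=list)
    peptides: list[PeptideConsensus] = field(default_factory=list)
    peptide_quant_layers: list[AssayQuantLayer] = field(default_factory=list)
    ratio_quant_layer: Optional[RatioQuantLayer] = None
    feature_lists: list[FeatureList] = field(default_factory=list)
    id: str = "SRM_doc"
    # raw lxml elements outside the SRM dialect, re-emitted on write
    extras: list[Any] = field(default_factory=list, compare=False)
    _counters: dict[str, int] = field(default_factory=dict, compare=False, repr=False)

    # -- id management -------------------------------------------------

    def next_id(self, kind: str) -> str:
        n = self._counters.get(kind, 0)
        self._counters[kind] = n + 1
        return f"{kind}_{n}"

    @property
    def label_mode(self) -> Optional[LabelMode]:
        return self.analysis_summary.label_mode

    # -- construction helpers -------------------------------------------

    def add_raw_file_group(self, location: str) -> RawFilesGroup:
        group = RawFilesGroup(id=self.next_id("rg"))
        group.raw_files.append(RawFile(id=self.next_id("raw"), location=location))
        self.raw_file_groups.append(group)
        return group

    def add_software(self, name: str, version: str) -> Software:
        sw = Software(id=self.next_id("sw"), name=name, version=version)
        self.software.append(sw)
        return sw

    def add_processing_step(
        self, software_ref: str, params: list[CvParam]
    ) -> DataProcessingStep:
        step = DataProcessingStep(
            id=self.next_id("dp"),
            software_ref=software_ref,
            order=len(self.data_processing) + 1,
            params=params,
        )
        self.data_processing.append(step)
        return step

    def add_assay(self, name: str, raw_file_ref: str, label: Label) -> Assay:
        label_param = param(
            cv.UNLABELED_SAMPLE if label is Label.LIGHT else cv.HEAVY_LABELED_SAMPLE
        )
        assay = Assay(
            id=self.next_id("ass"),
            name=name,
            raw_file_ref=raw_file_ref,
            label=label,
            label_param=label_param,
        )
        self.assays.append(assay)
        return assay

    def add_feature_list(self, raw_files_group_ref: str) -> FeatureList:
        fl = FeatureList(id=self.next_id("fl"), raw_files_group_ref=raw_files_group_ref)
        self.feature_lists.append(fl)
        return fl

    def add_feature(self, feature_list: FeatureList, feature: TransitionFeature) -> None:
        if feature.id in self.features_by_id():
            raise ValueError(f"duplicate feature id {feature.id}")
        feature_list.features.append(feature)

    def add_peptide(
        self, sequence: str, modifications: str, charge: int
    ) -> PeptideConsensus:
        pep = PeptideConsensus(
            id=self.next_id("pep"),
            sequence=sequence,
            modifications=modifications,
            charge=charge,
        )
        self.peptides.append(pep)
        return pep

    def add_protein(self, accession: str) -> ProteinEntry:
        prot = ProteinEntry(id=self.next_id("prot"), accession=accession)
        self.proteins.append(prot)
        return prot

    # -- lookups ---------------------------------------------------------

    def features_by_id(self) -> dict[str, TransitionFeature]:
        out: dict[str, TransitionFeature] = {}
        for fl in self.feature_lists:
            for ft in fl.features:
                out[ft.id] = ft
        return out

    def assay_by_id(self, assay_id: str) -> Optional[Assay]:
        for a in self.assays:
            if a.id == assay_id:
                return a
        return None

    def iter_features(self) -> Iterator[tuple[FeatureList, TransitionFeature]]:
        for fl in self.feature_lists:
            for ft in fl.features:
                yield fl, ft


def new_document(label_mode: LabelMode) -> SrmDocument:
    """An empty SRM document whose AnalysisSummary declares the technique
    ("SRM quantitation analysis") plus the design-mode term implied by
    ``label_mode``."""
    mode_term = (
        cv.LABEL_FREE_ANALYSIS
        if label_mode is LabelMode.LABEL_FREE
        else cv.MS1_LABEL_BASED_ANALYSIS
    )
    summary = AnalysisSummary(
        technique_terms=[param(cv.SRM_ANALYSIS), param(mode_term)],
        label_mode=label_mode,
    )
    return SrmDocument(analysis_summary=summary)


def resolve_references(doc: SrmDocument) -> list[Finding]:
    """Walk the document's reference graph; one ERROR Finding per dangler.

    An empty list means the graph is closed: every assay points at a
    declared raw-files group, every quant-layer row at a declared feature /
    peptide / protein, every evidence and ratio ref at a real target.
    """
    findings: list[Finding] = []

    def err(path: str, message: str) -> None:
        findings.append(Finding("R6", Severity.ERROR, path, message))

    group_ids = {g.id for g in doc.raw_file_groups}
    assay_ids = {a.id for a in doc.assays}
    feature_ids = set()
    for fl in doc.feature_lists:
        for ft in fl.features:
            feature_ids.add(ft.id)
    peptide_ids = {p.id for p in doc.peptides}
    protein_ids = {p.id for p in doc.proteins}
    ratio_ids = {r.id for r in doc.ratio_definitions}
    software_ids = {s.id for s in doc.software}

    for a in doc.assays:
        if a.raw_file_ref not in group_ids:
            err(
                f"AssayList/{a.id}",
                f"assay {a.id} references undeclared raw-files group "
                f"{a.raw_file_ref}",
            )
    for step in doc.data_processing:
        if step.software_ref not in software_ids:
            err(
                f"DataProcessingList/{step.id}",
                f"processing step {step.id} references unknown software "
                f"{step.software_ref}",
            )
    for fl in doc.feature_lists:
        if fl.raw_files_group_ref not in group_ids:
            err(
                f"FeatureList/{fl.id}",
                f"feature list {fl.id} references undeclared raw-files group "
                f"{fl.raw_files_group_ref}",
            )
        for layer in fl.quant_layers:
            for ref in layer.rows:
                if ref not in feature_ids:
                    err(
                        f"FeatureList/{fl.id}/FeatureQuantLayer/{layer.id}",
                        f"row references unknown feature {ref}",
                    )
    for pep in doc.peptides:
        for (assay_ref, _label), refs in pep.evidence.items():
            if assay_ref not in assay_ids:
                err(
                    f"PeptideConsensusList/{pep.id}",
                    f"evidence references unknown assay {assay_ref}",
                )
            for ref in refs:
                if ref not in feature_ids:
                    err(
                        f"PeptideConsensusList/{pep.id}",
                        f"evidence references unknown feature {ref}",
                    )
    for layer in doc.peptide_quant_layers:
        _check_assay_layer(layer, peptide_ids, assay_ids, "PeptideConsensusList", err)
    for layer in doc.protein_quant_layers:
        _check_assay_layer(layer, protein_ids, assay_ids, "ProteinList", err)
    for prot in doc.proteins:
        for ref in prot.peptide_refs:
            if ref not in peptide_ids:
                err(
                    f"ProteinList/{prot.id}",
                    f"protein {prot.id} references unknown peptide {ref}",
                )
    for ratio in doc.ratio_definitions:
        for ref in (ratio.numerator_ref, ratio.denominator_ref):
            if ref not in assay_ids:
                err(
                    f"RatioList/{ratio.id}",
                    f"ratio {ratio.id} references unknown assay {ref}",
                )
    rql = doc.ratio_quant_layer
    if rql is not None:
        for ref in rql.ratio_refs:
            if ref not in ratio_ids:
                err(
                    f"PeptideConsensusList/RatioQuantLayer/{rql.id}",
                    f"column references unknown ratio {ref}",
                )
        for ref in rql.rows:
            if ref not in peptide_ids:
                err(
                    f"PeptideConsensusList/RatioQuantLayer/{rql.id}",
                    f"row references unknown peptide {ref}",
                )
    return findings


def _check_assay_layer(layer, object_ids, assay_ids, section, err) -> None:
    path = f"{section}/AssayQuantLayer/{layer.id}"
    for ref in layer.assay_refs:
        if ref not in assay_ids:
            err(path, f"column references unknown assay {ref}")
    for ref in layer.rows:
        if ref not in object_ids:
            err(path, f"row references unknown object {ref}")


def _canonical_decimal(x: float) -> str:
    # the serialization grid: fixed decimal, 6 fractional digits
    if math.isnan(x):
        return "NaN"
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return "0" if s in ("", "-0") else s


def _values_equal(a: Any, b: Any) -> bool:
    if isinstance(a, float) and isinstance(b, float):
        if math.isnan(a) and math.isnan(b):
            return True
        # tolerance-0 comparison on the canonical decimal rendering: values
        # are stored exactly as parsed within the serialization contract
        return a == b or _canonical_decimal(a) == _canonical_decimal(b)
    if isinstance(a, dict) and isinstance(b, dict):
        return list(a) == list(b) and all(_values_equal(a[k], b[k]) for k in a)
    if isinstance(a, (list, tuple)) and isinstance(b, (list, tuple)):
        return len(a) == len(b) and all(_values_equal(x, y) for x, y in zip(a, b))
    if hasattr(a, "__dataclass_fields__") and hasattr(b, "__dataclass_fields__"):
        if type(a) is not type(b):
            return False
        for f in a.__dataclass_fields__.values():
            if not f.compare:
                continue
            if not _values_equal(getattr(a, f.name), getattr(b, f.name)):
                return False
        return True
    return a == b


def documents_equal(a: SrmDocument, b: SrmDocument) -> bool:
    """Field-by-field semantic equality; NaN compares equal to NaN (NaN is
    the serialized missing-value marker, so two documents carrying it in the
    same cell are the same document)."""
    return _values_equal(a, b)
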