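"""Semantic validation of SRM mzQuantML documents.

A file declares itself SRM through the AnalysisSummary technique terms;
the validator then applies the SRM-specific rules (required product-ion
descriptors on every Feature, label-mode / RatioList consistency) together
with the general structural rules SRM inherits (rectangular quant-layer
matrices, closed reference graph).  All problems are reported as Findings,
never exceptions, so a single pass lists everything wrong with a file.

Rule registry (closed, ordered):

====  =======  =============================================================
id    severity  check
====  =======  =============================================================
R1    ERROR    AnalysisSummary present with "SRM quantitation analysis"
R2    ERROR    exactly one of the two label-mode technique terms
R3    ERROR    every Feature carries "isolation window target m/z"
R4    ERROR    every Feature carries "local retention time" and "charge state"
R5    ERROR    every FeatureQuantLayer row length equals its column count
R6    ERROR    all cross-references resolve (no dangling ids)
R7    ERROR    label-free file has no RatioList and no RatioQuantLayer
R8    ERROR    labeled file: each Ratio has distinct assay num/denominator
R9    WARNING  peptide-level AssayQuantLayer present when features exist
R10   WARNING  peptide quantified nonzero in an assay has evidence there
====  =======  =============================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

from . import cv
from .model import (
    Finding,
    LabelMode,
    ObjectLevel,
    Severity,
    SrmDocument,
    resolve_references,
)


class Classification(NamedTuple):
    is_srm: bool
    label_mode: Optional[LabelMode]


def classify(doc: SrmDocument) -> Classification:
    """Detect technique and design mode from the AnalysisSummary terms
    (``label_mode`` is None when the terms do not determine it)."""
    summary = doc.analysis_summary
    is_srm = summary.has_term(cv.SRM_ANALYSIS)
    is_lf = summary.has_term(cv.LABEL_FREE_ANALYSIS)
    is_lb = summary.has_term(cv.MS1_LABEL_BASED_ANALYSIS)
    mode: Optional[LabelMode] = None
    if is_lf != is_lb:
        mode = LabelMode.LABEL_FREE if is_lf else LabelMode.MS1_LABEL_BASED
    return Classification(is_srm=is_srm, label_mode=mode)


@dataclass(frozen=True)
class Rule:
    rule_id: str
    severity: Severity
    description: str
    check: Callable[[SrmDocument], list[Finding]]

    def apply(self, doc: SrmDocument) -> list[Finding]:
        return [
            Finding(self.rule_id, self.severity, path, message)
            for path, message in self.check(doc)
        ]


def _r1(doc):
    if not doc.analysis_summary.has_term(cv.SRM_ANALYSIS):
        return [(
            "AnalysisSummary",
            'missing "SRM quantitation analysis" technique term',
        )]
    return []


def _r2(doc):
    summary = doc.analysis_summary
    n = sum(
        summary.has_term(t)
        for t in (cv.LABEL_FREE_ANALYSIS, cv.MS1_LABEL_BASED_ANALYSIS)
    )
    if n != 1:
        return [(
            "AnalysisSummary",
            'expected exactly one of "LC-MS label-free quantitation analysis" '
            f'or "MS1 label-based analysis", found {n}',
        )]
    return []


def _feature_param_rule(term_names):
    def check(doc):
        problems = []
        for fl, ft in doc.iter_features():
            for term in term_names:
                if ft.product_param(term) is None:
                    problems.append((
                        f"FeatureList/{fl.id}/Feature/{ft.id}",
                        f'feature {ft.id} lacks the required "{term}" cvParam',
                    ))
        return problems

    return check


def _r5(doc):
    problems = []
    for fl in doc.feature_lists:
        for layer in fl.quant_layers:
            n_cols = len(layer.columns)
            for ref, values in layer.rows.items():
                if len(values) != n_cols:
                    problems.append((
                        f"FeatureList/{fl.id}/FeatureQuantLayer/{layer.id}",
                        f"row {ref} has {len(values)} values for {n_cols} columns",
                    ))
    return problems


def _r6(doc):
    return [(f.element_path, f.message) for f in resolve_references(doc)]


def _r7(doc):
    if classify(doc).label_mode is not LabelMode.LABEL_FREE:
        return []
    problems = []
    if doc.ratio_definitions:
        problems.append((
            "RatioList",
            "label-free document must not contain a RatioList",
        ))
    if doc.ratio_quant_layer is not None:
        problems.append((
            f"PeptideConsensusList/RatioQuantLayer/{doc.ratio_quant_layer.id}",
            "label-free document must not contain a RatioQuantLayer",
        ))
    return problems


def _r8(doc):
    if classify(doc).label_mode is not LabelMode.MS1_LABEL_BASED:
        return []
    assay_ids = {a.id for a in doc.assays}
    problems = []
    for ratio in doc.ratio_definitions:
        path = f"RatioList/{ratio.id}"
        if ratio.numerator_ref == ratio.denominator_ref:
            problems.append(
                (path, f"ratio {ratio.id}: numerator and denominator are identical")
            )
        for ref in (ratio.numerator_ref, ratio.denominator_ref):
            if ref not in assay_ids:
                problems.append((
                    path,
                    f"ratio {ratio.id}: reference {ref} is not an assay "
                    "(numerator and denominator must be same-kind references)",
                ))
    return problems


def _r9(doc):
    has_features = any(fl.features for fl in doc.feature_lists)
    has_pep_layer = any(
        layer.object_level is ObjectLevel.PEPTIDE for layer in doc.peptide_quant_layers
    )
    if has_features and not has_pep_layer:
        return [(
            "PeptideConsensusList",
            "features are present but no peptide-level AssayQuantLayer was "
            "found; aggregation is expected",
        )]
    return []


def _r10(doc):
    evidence_assays = {
        pep.id: {assay_ref for (assay_ref, _label) in pep.evidence} for pep in doc.peptides
    }
    problems = []
    for layer in doc.peptide_quant_layers:
        for pep_id, values in layer.rows.items():
            for assay_ref, value in zip(layer.assay_refs, values):
                if value and assay_ref not in evidence_assays.get(pep_id, set()):
                    problems.append((
                        f"PeptideConsensusList/{pep_id}",
                        f"peptide {pep_id} is quantified nonzero in assay "
                        f"{assay_ref} but references no feature there",
                    ))
    return problems


RULES: tuple[Rule, ...] = (
    Rule("R1", Severity.ERROR,
         'AnalysisSummary carries "SRM quantitation analysis"', _r1),
    Rule("R2", Severity.ERROR,
         "AnalysisSummary carries exactly one label-mode term", _r2),
    Rule("R3", Severity.ERROR,
         'every Feature carries "isolation window target m/z"',
         _feature_param_rule((cv.ISOLATION_TARGET_MZ,))),
    Rule("R4", Severity.ERROR,
         'every Feature carries "local retention time" and "charge state"',
         _feature_param_rule((cv.LOCAL_RT, cv.CHARGE_STATE))),
    Rule("R5", Severity.ERROR,
         "FeatureQuantLayer rows match the column count", _r5),
    Rule("R6", Severity.ERROR, "all cross-references resolve", _r6),
    Rule("R7", Severity.ERROR,
         "label-free documents carry no RatioList/RatioQuantLayer", _r7),
    Rule("R8", Severity.ERROR,
         "Ratios relate two distinct assays", _r8),
    Rule("R9", Severity.WARNING,
         "peptide-level aggregation present when features exist", _r9),
    Rule("R10", Severity.WARNING,
         "nonzero peptide quantities are backed by feature evidence", _r10),
)


def validate_document(doc: SrmDocument) -> list[Finding]:
    """Apply the full registry in rule order; an empty list means valid."""
    findings: list[Finding] = []
    for rule in RULES:
        findings.extend(rule.apply(doc))
    return findings


def has_errors(findings: list[Finding]) -> bool:
    return any(f.severity is Severity.ERROR for f in findings)


def format_findings(findings: list[Finding], fmt: str = "tsv") -> str:
    """Render findings as a report: 'tsv' (one line per finding) or 'json'."""
    if fmt == "tsv":
        lines = ["rule_id\tseverity\tpath\tmessage"]
        lines += [
            f"{f.rule_id}\t{f.severity.value}\t{f.element_path}\t{f.message}"
            for f in findings
        ]
        return "\n".join(lines)
    if fmt == "json":
        import json

        return json.dumps(
            [
                {
                    "rule_id": f.rule_id,
                    "severity": f.severity.value,
                    "path": f.element_path,
                    "message": f.message,
                }
                for f in findings
            ],
            indent=2,
        )
    raise ValueError(f"unknown report format {fmt!r}")
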