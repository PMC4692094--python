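"""Controlled-vocabulary term table for the SRM mzQuantML dialect.

mzQuantML annotates elements with controlled-vocabulary (CV) parameters.
This module holds the small, closed set of PSI-MS term names the SRM
dialect uses, mapped to accessions where the accession is part of the
dialect contract.  Terms without an accession here are emitted as
``userParam`` elements (name-only vocabulary owned by this package);
everything else becomes a ``cvParam`` with ``cvRef="PSI-MS"``.

Matching (e.g. in the validator) goes accession-first and falls back to
an exact name comparison, so files that use the right accession with a
synonymous name still validate.
"""

from __future__ import annotations

# Technique terms carried by AnalysisSummary
SRM_ANALYSIS = "SRM quantitation analysis"
LABEL_FREE_ANALYSIS = "LC-MS label-free quantitation analysis"
MS1_LABEL_BASED_ANALYSIS = "MS1 label-based analysis"

# Product-ion (MS2) descriptors on a Feature, reused from TraML usage
LOCAL_RT = "local retention time"
ISOLATION_TARGET_MZ = "isolation window target m/z"
ISOLATION_LOWER_OFFSET = "isolation window lower offset"
ISOLATION_UPPER_OFFSET = "isolation window upper offset"
CHARGE_STATE = "charge state"

# FeatureQuantLayer column datatypes (the four Skyline measurements)
XIC_AREA = "XIC area"
XIC_BACKGROUND = "XIC background"
XIC_HEIGHT = "XIC height"
FWHM = "full width at half-maximum"

# Assay label markers
UNLABELED_SAMPLE = "unlabeled sample"
HEAVY_LABELED_SAMPLE = "heavy labeled sample"

# Aggregate-layer datatypes (method is recorded in the datatype term)
SUMMED_XIC_AREA = "summed XIC area"
MEAN_XIC_AREA = "mean XIC area"
WEIGHTED_MEAN_XIC_AREA = "weighted mean XIC area"
SUMMED_PEPTIDE_VALUE = "summed peptide abundance"
MEAN_PEPTIDE_VALUE = "mean peptide abundance"
RATIO_LIGHT_HEAVY = "light:heavy peptide ratio"

SKYLINE = "Skyline"

#: name -> PSI-MS accession; ``None`` means the term is a userParam of
#: this dialect (no verified accession is claimed for it).
TERM_ACCESSIONS: dict[str, str | None] = {
    SRM_ANALYSIS: "MS:1001838",
    LABEL_FREE_ANALYSIS: "MS:1001834",
    MS1_LABEL_BASED_ANALYSIS: "MS:1002018",
    LOCAL_RT: "MS:1000895",
    ISOLATION_TARGET_MZ: "MS:1000827",
    ISOLATION_LOWER_OFFSET: "MS:1000828",
    ISOLATION_UPPER_OFFSET: "MS:1000829",
    CHARGE_STATE: "MS:1000041",
    XIC_AREA: "MS:1001858",
    FWHM: "MS:1000086",
    UNLABELED_SAMPLE: "MS:1002038",
    SKYLINE: "MS:1000922",
    XIC_BACKGROUND: None,
    XIC_HEIGHT: None,
    HEAVY_LABELED_SAMPLE: None,
    SUMMED_XIC_AREA: None,
    MEAN_XIC_AREA: None,
    WEIGHTED_MEAN_XIC_AREA: None,
    SUMMED_PEPTIDE_VALUE: None,
    MEAN_PEPTIDE_VALUE: None,
    RATIO_LIGHT_HEAVY: None,
}

_ACCESSION_TO_NAME = {a: n for n, a in TERM_ACCESSIONS.items() if a is not None}


def accession_for(name: str) -> str | None:
    """Accession of a dialect term name, or None for name-only terms."""
    return TERM_ACCESSIONS.get(name)


def same_term(accession: str | None, name: str, term_name: str) -> bool:
    """True if (accession, name) denotes the dialect term ``term_name``.

    Accession wins when both sides have one; otherwise exact name match.
    """
    ref = TERM_ACCESSIONS.get(term_name)
    if ref is not None and accession is not None:
        return accession == ref
    return name == term_name
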