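"""Shared fixtures: small synthetic SRM experiments run through the full
parse -> build pipeline, plus a reusable corpus of random documents."""

from __future__ import annotations

import pytest

from srmzq.quantify import AggregationSpec
from srmzq.skyline_import import build_document, parse_report
from srmzq.synthgen import SynthSpec, SynthResult, generate


def make_experiment(
    seed: int = 0,
    labeled: bool = False,
    noise_sigma: float = 0.0,
    n_proteins: int = 2,
    peptides_per_protein: int = 2,
    transitions_per_peptide: int = 3,
    n_replicates: int = 2,
    true_ratio: float = 2.0,
    spec: AggregationSpec | None = None,
):
    """Generate a small experiment and convert it; returns (result, rows, doc)."""
    result = generate(
        SynthSpec(
            n_proteins=n_proteins,
            peptides_per_protein=peptides_per_protein,
            transitions_per_peptide=transitions_per_peptide,
            n_replicates=n_replicates,
            labeled=labeled,
            true_ratio=true_ratio,
            noise_sigma=noise_sigma,
            seed=seed,
        )
    )
    rows = parse_report(result.report_csv)
    doc = build_document(rows, spec=spec)
    return result, rows, doc


@pytest.fixture
def label_free_doc():
    return make_experiment(seed=11, labeled=False)[2]


@pytest.fixture
def labeled_doc():
    return make_experiment(seed=12, labeled=True)[2]


@pytest.fixture(scope="session")
def corpus() -> list[tuple[SynthResult, object]]:
    """100 random small experiments (alternating design, varying shape and
    noise) converted to documents."""
    docs = []
    for seed in range(100):
        result, _rows, doc = make_experiment(
            seed=seed,
            labeled=bool(seed % 2),
            noise_sigma=0.0 if seed % 3 == 0 else 0.2,
            n_proteins=1 + seed % 3,
            peptides_per_protein=1 + seed % 2,
            transitions_per_peptide=2 + seed % 3,
            n_replicates=1 + (seed % 4) // 2,
        )
        docs.append((result, doc))
    return docs
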