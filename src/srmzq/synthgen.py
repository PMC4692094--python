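"""Synthetic SRM experiments with known ground truth.

Emulates the Skyline transition report of a targeted experiment: a protein
panel, a few proteotypic peptides per protein, several transitions per
peptide, measured across replicates, optionally in a light/heavy labeled
design with a known true abundance ratio.  Per-transition XIC areas are
``base_area x label_factor x exp(N(0, sigma^2))`` (multiplicative
log-normal noise, the usual model for XIC peak areas), with
``label_factor = true_ratio`` for the light channel and 1 for heavy.
Retention time and peak width are drawn once per peptide and shared by its
transitions, as co-eluting transitions of one precursor are.

The ground truth (expected per-assay summed area and per-replicate
light/heavy ratio) is computed inside the generator by direct summation
over the emitted rows, independently of :mod:`srmzq.quantify`, so the
aggregation pipeline can be checked against it.

Randomness comes from NumPy's default PCG64 generator seeded with
``spec.seed``; the same spec yields byte-identical CSV output.  What this
generator does not emulate: chromatographic peak shapes, interfering
transitions, missing peaks, retention-time drift between replicates, or
between-replicate biological variance — noise is i.i.d. per transition
instance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .mzq_io import format_number

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HEADER = (
    "ProteinName,PeptideModifiedSequence,PrecursorMz,PrecursorCharge,"
    "ProductMz,ProductCharge,FragmentIon,IsotopeLabelType,ReplicateName,"
    "FileName,RetentionTime,Area,Background,Height,Fwhm"
)


@dataclass
class SynthSpec:
    """Design of one synthetic experiment.

    true_ratio is the light/heavy abundance ratio (labeled designs only);
    noise_sigma is the standard deviation of the log-normal multiplicative
    noise on XIC areas (0 = noise-free); base_area is the heavy-channel
    (or label-free) expected area in arbitrary XIC-area units.
    """

    n_proteins: int = 4
    peptides_per_protein: int = 3
    transitions_per_peptide: int = 5
    n_replicates: int = 3
    labeled: bool = False
    true_ratio: float = 2.0
    base_area: float = 10000.0
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "peptides_per_protein",
                     "transitions_per_peptide", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")


@dataclass
class PeptideTruth:
    sequence: str
    charge: int
    protein: str
    #: assay key -> expected summed XIC area; keys are the converter's assay
    #: names (replicate name, or "<replicate>_<light|heavy>" when labeled)
    per_assay: dict[str, float] = field(default_factory=dict)
    #: replicate name -> expected light/heavy ratio of summed areas
    ratios: dict[str, float] = field(default_factory=dict)


@dataclass
class SynthResult:
    spec: SynthSpec
    report_csv: str
    truth: dict[tuple[str, int], PeptideTruth]


def generate(spec: SynthSpec) -> SynthResult:
    """Deterministically generate a report CSV plus its ground truth."""
    rng = np.random.default_rng(spec.seed)

    labels = ["light", "heavy"] if spec.labeled else ["light"]
    replicates = [f"rep_{i + 1}" for i in range(spec.n_replicates)]

    # panel layout, drawn once and shared by all replicates
    peptides = []  # (protein, sequence, charge, prec_mz, rt, fwhm, transitions)
    seen_seqs: set[str] = set()
    for p in range(spec.n_proteins):
        protein = f"PROT_{p + 1}"
        for _ in range(spec.peptides_per_protein):
            while True:
                length = int(rng.integers(8, 16))
                seq = "".join(
                    AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)
                )
                if seq not in seen_seqs:
                    seen_seqs.add(seq)
                    break
            charge = int(rng.integers(2, 4))
            prec_mz = float(rng.uniform(300.0, 1500.0))
            rt = float(rng.uniform(5.0, 60.0))
            fwhm = float(rng.uniform(0.05, 0.3))
            transitions = [
                (f"y{t + 3}", float(rng.uniform(300.0, 1500.0)))
                for t in range(spec.transitions_per_peptide)
            ]
            peptides.append((protein, seq, charge, prec_mz, rt, fwhm, transitions))

    buf = io.StringIO()
    buf.write(HEADER + "\r\n")
    truth: dict[tuple[str, int], PeptideTruth] = {
        (seq, charge): PeptideTruth(sequence=seq, charge=charge, protein=protein)
        for protein, seq, charge, *_ in peptides
    }

    for rep in replicates:
        for label in labels:
            assay_key = f"{rep}_{label}" if spec.labeled else rep
            factor = spec.true_ratio if (spec.labeled and label == "light") else 1.0
            for protein, seq, charge, prec_mz, rt, fwhm, transitions in peptides:
                total = 0.0
                for fragment, prod_mz in transitions:
                    noise = float(rng.normal(0.0, spec.noise_sigma))
                    area = spec.base_area * factor * float(np.exp(noise))
                    area_s = format_number(area)
                    background = 0.02 * area
                    height = area / (1.064 * fwhm)
                    buf.write(
                        f"{protein},{seq},{format_number(prec_mz)},{charge},"
                        f"{format_number(prod_mz)},1,{fragment},{label},{rep},"
                        f"{rep}.raw,{format_number(rt)},{area_s},"
                        f"{format_number(background)},{format_number(height)},"
                        f"{format_number(fwhm)}\r\n"
                    )
                    # truth sums what the file actually says (the formatted value)
                    total += float(area_s)
                truth[(seq, charge)].per_assay[assay_key] = total

    if spec.labeled:
        for pep in truth.values():
            for rep in replicates:
                heavy = pep.per_assay[f"{rep}_heavy"]
                light = pep.per_assay[f"{rep}_light"]
                pep.ratios[rep] = light / heavy if heavy else float("nan")

    return SynthResult(spec=spec, report_csv=buf.getvalue(), truth=truth)


def truth_table(result: SynthResult) -> str:
    """Ground truth as a tab-separated sidecar (one line per peptide/assay,
    plus one per peptide/replicate ratio in labeled designs)."""
    lines = ["peptide\tcharge\tprotein\tkind\tkey\tvalue"]
    for (seq, charge), pep in result.truth.items():
        for assay_key, value in pep.per_assay.items():
            lines.append(
                f"{seq}\t{charge}\t{pep.protein}\tsum\t{assay_key}\t{format_number(value)}"
            )
        for rep, ratio in pep.ratios.items():
            lines.append(
                f"{seq}\t{charge}\t{pep.protein}\tratio\t{rep}\t{format_number(ratio)}"
            )
    return "\n".join(lines) + "\n"
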