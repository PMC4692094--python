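# srmzq — SRM quantitative data in the mzQuantML standard

`srmzq` represents the output of **selected reaction monitoring (SRM)**
quantification software in the PSI **mzQuantML 1.0.1** XML standard, for
targeted-proteomics practitioners and tool authors who need to exchange,
validate or post-process SRM results.

In an SRM experiment a triple-quadrupole instrument monitors *transitions*
— precursor ion m/z → product ion m/z pairs — and the area of each
transition's extracted ion chromatogram (XIC) is the quantitative signal.
mzQuantML was designed around MS1 features, so the SRM dialect encodes each
transition as a `<Feature>` whose attributes (`rt`, `mz`, `charge`) carry
the MS1 precursor and whose CV parameters carry the MS2 product:

| | MS1 (attribute of `<Feature>`) | MS2 (`<cvParam>` of `<Feature>`) |
|---|---|---|
| retention time | `rt` (or `"null"` if unknown) | local retention time |
| m/z | `mz` | isolation window target m/z |
| charge | `charge` | charge state |

Per-transition measurements (XIC area, background, height, FWHM) live in a
multi-column `<FeatureQuantLayer>`. Peptide-level values are derived by
aggregating a peptide's transitions per assay,

&nbsp;&nbsp;&nbsp;&nbsp;`sum`: x_pep = Σᵢ aᵢ &nbsp;&nbsp; `mean`: x_pep = (1/n) Σᵢ aᵢ &nbsp;&nbsp; `weighted mean`: x_pep = Σᵢ wᵢaᵢ / Σᵢ wᵢ,

and stored in a single-datatype `<AssayQuantLayer>`. In a labeled design
each replicate contributes a *light* and a *heavy* assay, and the peptide
ratio per replicate is r = x_light / x_heavy, stored in a
`<RatioQuantLayer>` against per-replicate `<Ratio>` definitions. Label-free
files carry no `<RatioList>` at all. A semantic validator (rules R1–R10,
see `docs/methods.md`) enforces the SRM-specific contract: technique terms
in `<AnalysisSummary>`, the three required product descriptors on every
feature, rectangular data matrices, a closed reference graph and
label-mode/ratio consistency.

The package provides:

- `srmzq.model` — the document model (features, quant layers, peptides,
  ratios, findings);
- `srmzq.mzq_io` — canonical (byte-deterministic) mzQuantML writer and a
  tolerant reader;
- `srmzq.skyline_import` — converter for Skyline-style transition report
  CSVs;
- `srmzq.quantify` — transition→peptide→protein aggregation and
  light/heavy ratios;
- `srmzq.validate` — the SRM semantic rule registry;
- `srmzq.synthgen` — synthetic SRM experiments with ground truth;
- `srmzq.cli` — the `srmzq` command (`convert`, `validate`, `summarize`,
  `synth`).

## Worked example

Generate a small labeled experiment (1 protein, 2 peptides, 3 transitions,
2 replicates, true light/heavy ratio 2.5, 10 % multiplicative noise),
convert it and inspect the quantitative layers:

```python
from srmzq import (SynthSpec, generate, parse_report, build_document,
                   write_mzq, validate_document)

res = generate(SynthSpec(n_proteins=1, peptides_per_protein=2,
                         transitions_per_peptide=3, n_replicates=2,
                         labeled=True, true_ratio=2.5, noise_sigma=0.1,
                         seed=42))
doc = build_document(parse_report(res.report_csv))
print("findings:", validate_document(doc))

layer = doc.peptide_quant_layers[0]
names = {a.id: a.name for a in doc.assays}
for pep in doc.peptides:
    print(pep.id, pep.sequence, "/%d" % pep.charge)
    for aref, v in zip(layer.assay_refs, layer.rows[pep.id]):
        print("   ", names[aref], round(v, 1))
    print("   ratios:", [round(v, 3) for v in doc.ratio_quant_layer.rows[pep.id]])
```

prints

```
findings: []
pep_0 SQKKVCQF /2
    rep_1_light 72703.4
    rep_1_heavy 32430.2
    rep_2_light 75690.1
    rep_2_heavy 30149.2
   ratios: [2.242, 2.511]
pep_1 WSPKTMKLF /2
    rep_1_light 78350.8
    rep_1_heavy 29354.5
    rep_2_light 76631.0
    rep_2_heavy 31249.0
   ratios: [2.669, 2.452]
```

`findings: []` means the document satisfies every SRM rule. Each peptide
row shows the summed XIC area per assay (light sums ≈ 2.5× heavy sums, as
designed) and the per-replicate light/heavy ratios, which scatter around
the true value 2.5 because of the 10 % area noise. `write_mzq(doc)` yields
the corresponding mzQuantML file (here ~20 kB), which opens with:

```xml
<?xml version='1.0' encoding='UTF-8'?>
<MzQuantML xmlns="http://psidev.info/psi/pi/mzQuantML/1.0" id="SRM_doc" version="1.0.1">
  ...
  <AnalysisSummary>
    <cvParam cvRef="PSI-MS" accession="MS:1001838" name="SRM quantitation analysis"/>
    <cvParam cvRef="PSI-MS" accession="MS:1002018" name="MS1 label-based analysis"/>
  </AnalysisSummary>
```

The same workflow from the shell:

```sh
srmzq synth report.csv --labeled --seed 42 --truth-out truth.tsv
srmzq convert report.csv out.mzq          # exit 0, file validates
srmzq validate out.mzq                    # exit 0 valid, 2 on ERRORs
srmzq summarize out.mzq --export-layer aql_0
```

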