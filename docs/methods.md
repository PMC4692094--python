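# Methods

## The encoding

Selected reaction monitoring quantifies a peptide through a handful of
transitions (precursor m/z → product m/z pairs); the measured value per
transition is the area (sometimes height) of its extracted ion
chromatogram. mzQuantML's core objects were designed for MS1 features, so
the SRM dialect splits each transition across the two domains of a
`<Feature>`:

- **MS1 (precursor)** — the `rt`, `mz`, `charge` attributes. Skyline-style
  reports give a product-trace retention time, not a precursor one, so the
  converter always writes `rt="null"`; in the model an unknown precursor RT
  is an absent optional (`None`), never a sentinel number.
- **MS2 (product)** — three required CV parameters: *isolation window
  target m/z* (the Q3-selected product m/z), *local retention time*
  (minutes) and *charge state*; optionally the isolation-window offset
  terms.

Per-transition measurements go into a `FeatureQuantLayer`, the one
QuantLayer kind allowed several column datatypes; all peptide/protein
layers are single-datatype. Every matrix row must have exactly as many
values as declared columns (enforced at construction and again as
validator rule R5), which is why missing measurements are encoded rather
than dropped: absent input cells become 0 in feature matrices, and an
undefined ratio becomes NaN (serialized `"NaN"`), to be treated as missing
downstream.

## Converter rules (Skyline-style report → mzQuantML)

The accepted report dialect is a 15-column CSV (see
`srmzq.skyline_import.COLUMNS`); only `IsotopeLabelType` has fixed
semantics in the upstream format — label-free files say `light` on every
row, labeled files mix `light`/`heavy` — so label mode is detected by
exactly that predicate. The other 14 names follow Skyline's conventional
report vocabulary and are this package's documented contract.

- One `RawFilesGroup` and one `Assay` per distinct (replicate, label)
  pair; the light and heavy channels of a replicate are distinct assays so
  that ratios can be assay-versus-assay, as the Ratio object requires.
  Labeled assays are named `<replicate>_<light|heavy>`; this naming is the
  dialect's mechanism for pairing a replicate's channels when computing
  ratios.
- One `Feature` per transition instance, keyed by (replicate, modified
  sequence, precursor charge, fragment ion, product charge, label); a
  repeated key is rejected as an ambiguous feature.
- One four-column `FeatureQuantLayer` per raw-files group, in the fixed
  order *XIC area, XIC background, XIC height, full width at
  half-maximum* — the four measurement datatypes a Skyline report carries.
- One `PeptideConsensus` per (modified sequence, precursor charge),
  spanning both label channels, with evidence references keyed by
  (assay, label). Peptide identity includes the charge because different
  charge states are acquired as distinct transitions. The modification
  descriptor is canonical: sorted `position:name` pairs parsed from the
  bracketed Skyline sequence (`PEPT[+80]IDEK` → `4:+80`; position 0 is
  N-terminal). Names must not contain `;` or `:`.
- The peptide `AssayQuantLayer` is computed by summing XIC areas (below);
  labeled documents additionally get per-replicate `Ratio` definitions and
  a `RatioQuantLayer`. Label-free documents get neither.
- A `DataProcessing` step records the converter version, the aggregation
  method and the ratio orientation.

All identifiers are `<kind>_<ordinal>` in insertion order, so converting
the same input twice yields byte-identical XML.

## Aggregation and ratios

Peptide value per assay = method over the XIC areas of the peptide's
features in that assay: `SUM` (default — the converter's standard
behaviour), `MEAN`, or `WEIGHTED_MEAN` (weights from a chosen column,
XIC area by default; an all-zero weight cell yields 0 plus a warning).
Peptides without evidence in an assay get 0 to keep the matrix
rectangular. Protein values aggregate peptide values (`SUM` default or
`MEAN`); a protein with no quantified peptides is excluded with a warning.

Ratios are computed on the aggregated values — sum first, then divide —
one ratio per replicate, numerator = light (flippable via
`--flip-ratio`/`flip=`; the orientation is a convention, not a property of
the data). A zero denominator yields NaN with a warning. Division-first
versus sum-first matters only under noise; summing first weights each
transition by its signal and is what summation-based converters produce.

## Validator

The registry is closed and ordered; findings are returned in rule order
then document order, ERRORs make a file invalid, WARNINGs do not.

| id | severity | rule |
|----|----------|------|
| R1 | ERROR | AnalysisSummary carries "SRM quantitation analysis" |
| R2 | ERROR | exactly one of the two label-mode terms |
| R3 | ERROR | every Feature carries "isolation window target m/z" |
| R4 | ERROR | every Feature carries "local retention time" and "charge state" |
| R5 | ERROR | FeatureQuantLayer rows match the column count |
| R6 | ERROR | all cross-references resolve |
| R7 | ERROR | label-free: no RatioList / RatioQuantLayer |
| R8 | ERROR | labeled: each Ratio relates two distinct assays |
| R9 | WARNING | peptide layer present when features exist |
| R10 | WARNING | nonzero peptide values backed by feature evidence |

R5/R6 are the general structural rules every mzQuantML technique inherits;
the remaining general CV-mapping machinery of the original multi-technique
validator is out of scope here, replaced by this closed registry. R4 is
graded ERROR because the product descriptors are required for the file to
be interpretable as SRM at all; the R9/R10 WARNING grading is this
package's choice (missing aggregation or unevidenced values are suspicious
but not malformed). Quantification-side warnings carry operational ids
Q1 (all-zero weights), Q2 (zero ratio denominator), Q3 (protein without
peptides) in the same Finding type.

CV terms are matched accession-first with exact-name fallback, against a
small internal table (`srmzq.cv`). Terms whose PSI-MS accession is part of
the contract carry it (e.g. `MS:1000827` isolation window target m/z,
`MS:1001838` SRM quantitation analysis); a few datatype terms of this
dialect (XIC background, XIC height, the aggregation-method datatypes, the
heavy-label marker) are name-only and serialize as `userParam` — no
accession is claimed where none was verified.

## Serialization

Fixed element order (CvList, AnalysisSummary, InputFiles, SoftwareList,
DataProcessingList, AssayList, RatioList?, ProteinList?,
PeptideConsensusList, FeatureList*), fixed attribute order, fixed
namespace prefixing, and canonical number rendering: fixed decimal with a
`.` separator, at most 6 fractional digits, trailing zeros stripped, no
exponent notation in the supported range (numbers live in
[1e-4, 1e7) — m/z, minutes, XIC areas), NaN as `NaN`. Values re-serialize
from parsed numbers, not original lexical forms, and semantic equality for
round trips compares on exactly this grid (tolerance 0 at the serialized
precision): in-memory aggregates can carry more binary precision than the
6-decimal rendering, and the grid is the contract. With this convention
`write(read(write(doc))) == write(doc)` byte-for-byte.

The reader accepts any well-formed mzQuantML: unknown top-level elements
(StudyVariableList, Provider, …) are retained opaquely and re-emitted
after the recognized sections — content-preserving, not
position-preserving. Structural violations that make a file unusable
(missing AnalysisSummary, ragged matrix rows, duplicate feature ids) raise
immediately with the offending layer/row named; everything semantic is a
validator Finding. Validation against an official XSD is optional
(`SerializationOptions.schema_location`, via lxml) so the package stays
self-contained; the internal structural checks always run.

## Synthetic experiments

`srmzq.synthgen` emulates the transition report of a targeted panel:
`n_proteins` (default 4) × `peptides_per_protein` (3) ×
`transitions_per_peptide` (5) × `n_replicates` (3), optionally labeled
with a true light/heavy ratio (default 2.0). Per-transition area =
`base_area · label_factor · exp(N(0, σ²))` — multiplicative log-normal
noise (σ default 0.2, a realistic XIC-area CV for SRM), label_factor =
true_ratio for light and 1 for heavy, base_area default 10 000 arbitrary
area units. Sequences are random 8–15-mers over the 20-letter alphabet;
m/z values uniform in [300, 1500] Th; retention time (uniform 5–60 min)
and FWHM (0.05–0.3 min) are drawn once per peptide and shared by its
transitions, as co-eluting traces of one precursor are. Randomness is
NumPy's default PCG64 generator seeded from `spec.seed`; the same spec
yields byte-identical CSV.

Ground truth (per-assay summed area, per-replicate ratio) is computed
inside the generator by direct summation over the emitted, *formatted*
values — independent of the aggregation code — so pipeline output can be
compared exactly at σ = 0 and to a brute-force oracle otherwise.

What the generator does **not** emulate: chromatographic peak shape,
interfering/shared transitions, missing peaks, retention-time drift,
between-sample biological variance, or detector saturation. Passing tests
therefore demonstrate the correctness of the encoding, conversion,
aggregation and validation logic under the stated noise model — not
robustness to the messiness of real acquisitions.

## Numerical and design notes

- Test and verification problem sizes: the randomized corpora use 100
  small documents (1–3 proteins, 1–2 peptides each, 2–4 transitions, 1–2
  replicates, half labeled); the ratio-recovery check pools peptide ratios
  from 50 seeded single-replicate experiments at σ = 0.2 with 5
  transitions and compares the pooled median against the truth within
  3σ/√5. These sizes exercise every code path while keeping the suite
  near-instant.
- Ties/ordering: all document collections preserve insertion order
  (first-appearance order of the input rows), which fixes matrix row
  order, assay column order and protein order deterministically.
- Degenerate inputs: header-only reports parse to an empty list but cannot
  be converted (no rows → no mode); a peptide absent from an assay is 0,
  not missing; 0/0 and x/0 ratios are NaN.
- Exit codes of the CLI are stable: 0 success/valid, 1 usage or I/O
  error, 2 validation ERRORs; a convert run validates its own output and
  refuses to write an invalid file.

## Known limitations

- StudyVariables and their quant layers are accepted on read (as opaque
  extras) but never produced; small-molecule lists and mzIdentML
  cross-links are out of scope.
- Only the SRM dialect is validated; files of other mzQuantML techniques
  pass through the reader tolerantly but the rule registry is not meant
  for them.
- The reader targets the SRM subset plus pass-through; it is not a
  complete implementation of every element of the official schema.
- Chromatogram-level traces, interference correction, peak-probability
  scoring, RT alignment and cross-run normalization are explicitly not
  implemented.
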