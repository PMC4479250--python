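# Methods

## The archive model

A QDB archive is five ordered registries — compounds, properties,
descriptors, models, predictions — of identified containers, plus
archive-level metadata and an optional BibTeX-style bibliography entry.
Container ids follow the grammar `^[a-z0-9][a-z0-9-]*$` (filesystem- and
URL-safe). Tabular data lives in a `values` cargo: two-column TSV,
`compound-id <TAB> value`, where a value is decimal text, a categorical
label, or the missing marker `N/A`. Values are held in memory as their exact
cargo text and re-emitted verbatim, so archives round-trip byte-identically
and no floating-point reformatting can masquerade as a data change. Two
reference semantics apply: *strong* references (model → property, model →
descriptors, prediction → model) must resolve; *weak* references (the
compound-id keys of a values cargo) are data whose resolution the validator
reports.

On disk the archive is a ZIP container (or unpacked directory): `archive.xml`
at the root, one registry XML per kind (`compounds/compounds.xml`, …), cargo
payloads at `<registry>/<id>/<cargo-name>`, and optionally
`bibliography.bib`. Writing is deterministic — fixed entry order, epoch
timestamps, stored (uncompressed) entries — so equal archives have equal
SHA-256 digests, which the tests exploit. The reader is deliberately lenient
(a declared cargo with no data entry loads as a `None` payload); the
validator is strict. The "internal" variant produced by `normalize_internal`
re-serializes values cargos in compound-registry order and attaches each
model's precomputed AD parameters as a JSON `derived` cargo; the pass is
idempotent and never fails — models whose AD cannot be estimated simply get
no derived cargo.

## Validation

Findings are (severity, level, check id, container path, message); outcome is
*failed* iff any ERROR, *warnings* iff only warnings, else *clean*. Each
level runs all lower levels, which makes the finding set monotone in the
level by construction.

- **Basic**: missing optional attributes (name, description, labels) are
  warnings; everything else is an error — declared-but-absent cargos,
  unparseable values cargos, non-numeric descriptor values, malformed or
  checksum-failing CAS numbers, InChI syntax violations, missing `values`
  cargos on properties/descriptors/predictions, missing or unparseable
  equation cargos on models, unresolved strong references, unresolved weak
  keys, invalid prediction set kinds.
- **Intermediate**: missing compound InChI, missing endpoint
  category/name or UCUM cargo on a property, missing descriptor
  application are errors; two compounds sharing one InChI is a warning
  (ambiguous identity, but the archive remains usable).
- **Advanced**: each model is re-evaluated per compound from its stored
  descriptor values and compared against each stored prediction value.

**CAS check**: the registry check digit — the sum of the body digits
weighted by position from the right (1-based) modulo 10 — on top of the
`2–7 digits / 2 digits / 1 digit` shape. **InChI check**: purely syntactic —
`InChI=1` or `InChI=1S`, a non-empty formula layer of letters/digits/dots,
then zero or more letter-prefixed layers. Semantic verification would need a
chemistry engine, which is deliberately kept out of the validation path so
basic validation runs dependency-free.

**Advanced tolerance**: stored values carry finite printed precision, so a
recomputed value is accepted within half a unit in the last decimal place of
the stored text (computed from the decimal exponent, so exponent notation is
handled), with an absolute floor of 1e-8 to absorb float round-off on
full-precision text. Categorical predictions must match exactly.

## Equations and statistics

The equation cargo is a header line (`type=regression` or
`type=classification; cuts=…; labels=…`) followed by one expression over
descriptor ids with `+ - * / ^` (power right-associative, binding tighter
than unary minus), parentheses, and `ln`, `log10`, `exp`, `sqrt`, `abs`.
The parser is a ~60-line recursive descent over this fixed grammar; keeping
the dialect small makes reproducibility testing auditable and portable.
Classification is a thresholded regression score: with strictly increasing
cuts c₁<…<cₖ and k+1 labels, score ≤ cᵢ selects label i, otherwise the last
label. Domain errors (log of a non-positive value, division by zero,
non-finite results) raise rather than propagate NaNs.

Regression statistics over the common non-missing keys: R² = 1 − SS_res/SS_tot,
RMSE = √(SS_res/n), MAE. R² may be negative on external sets and is reported
as computed; an all-equal experimental vector makes R² undefined and is an
explicit error, never silently 0. Confusion matrices use the sorted union of
observed labels, rows = actual. Statistics are computed per prediction set,
since training/validation/testing performance answers different questions.

## Applicability domain

Leverage uses the intercept-augmented training design (column of ones):
h(x) = [1,x](XᵀX)⁻¹[1,x]ᵀ, warning threshold h\* = 3(d+1)/n — the standard
Williams-plot convention. Mahalanobis distance uses the training centroid
and sample covariance (divisor n−1). Both are estimated from **training-set
compounds only** (complete descriptor rows), so validation/testing/external
points are scored against the space the model was actually fitted in.
Singular designs fall back to the Moore–Penrose pseudo-inverse with a
`singular` flag rather than crashing on degenerate archives. Standardized
residuals divide by training RMSE. Williams data carries one profile per
predicted compound in registry order; compounds without an experimental
value keep their distances but no residual (the Gramatica/Insubria points).
The domain flag on predictions uses the leverage criterion only
(h ≤ h\*); Mahalanobis is reported but not thresholded — one documented
cutoff beats two undocumented ones. Similarity is raw Euclidean distance
over the model's descriptors (an optional z-score flag exists), ties broken
by registry order, default k = 5.

## Prediction workflow

Structure input follows the three-step pipeline — prepare the structure
text, compute descriptors, evaluate the equation. Descriptor calculators are
plugins keyed by an application string; the built-in table-driven
`mock/1.0` calculator serves tests and demos, and declining a descriptor is
explicit (absent key), never a silent zero, so callers can fall back to
manual entry. Manual and stored modes skip the first two steps. Batch mode
is record-wise: one failure is recorded in place and never aborts the batch,
and a batch is exactly the concatenation of the equivalent single calls.

## Synthetic archives

The generator emulates a deposited linear QSAR study: descriptor values are
independent normals (defaults: `logp` ~ N(1.5, 1), `mw` ~ N(150, 40)), the
experimental endpoint is intercept + weights · descriptors + N(0, noise_sd)
with defaults (0.8, 0.55, −0.01) and noise 0.25 — giving a training R²
around 0.9, typical of published toxicity models — and stored predictions
are computed by the archived equation itself from the stored (printed)
descriptor values, so defect-free archives are reproducible by construction.
The default archive has 32 compounds split 70/15/15 into
training/validation/testing by a seeded shuffle. Compound identifiers are
checksum-valid CAS numbers and syntactically valid InChIs: a small pool of
genuine simple-molecule InChIs, extended beyond the pool with unique
formula-only n-alkane InChIs so that no two compounds share an identifier
(duplicate InChIs would trip the intermediate-level uniqueness warning).
Numbers are rendered as shortest round-trip decimal text.

Randomness uses a self-contained splitmix64 generator with Box–Muller
normals and Fisher–Yates shuffling — fully specified so another
implementation can reproduce an archive byte-for-byte from the seed alone.

Defect tokens each break exactly one validation level: `bad-cas`,
`orphan-cargo`, `dangling-weak-ref` (basic); `drop-inchi`,
`drop-application`, `drop-ucum`, `drop-endpoint` (intermediate);
`tamper-prediction` (advanced, +1.0 on one stored value, or a flipped label
for classifiers); `drop-name` (warnings only).

What the generator does **not** emulate: real chemical diversity, correlated
descriptors, nonlinear structure–activity relationships, or measurement
error structure beyond i.i.d. Gaussian noise. Passing tests therefore
demonstrate the *mechanics* — format fidelity, validation semantics,
reproducibility arithmetic, AD algebra — not predictive performance on real
chemistry.

## Problem sizes and numerical choices

The test and acceptance suites use 50 random archives (8–24 compounds, 1–3
descriptors) for round-trip and monotonicity properties, 100 random 5–20 ×
1–4 designs for the AD oracle comparisons (agreement to 1e-10 relative
against an independent dense solve, hat-trace ≈ rank and Σd² = (n−1)·d
identities to 1e-8), 20 random fixtures for predictor self-consistency, and
1000-candidate fuzz sets for the CAS and InChI oracles; OLS recovery uses
n = 200 at noise 0.1 with a 5-standard-error bound computed from the known
noise level. These sizes give each property many independent chances to
fail while the whole suite stays interactive.

## Known limitations

- The equation dialect covers explicit algebraic models only — no PMML, no
  tree/SVM/neural families.
- UCUM unit strings are checked for presence, not grammar.
- InChI/CAS validation is syntactic; chemical identity is out of scope.
- The Mahalanobis covariance is training-only by design; repositories that
  use whole-dataset covariance will score borderline points differently.
- Batch TSV input assumes one input mode per file (structure column,
  compound column, or descriptor columns).
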