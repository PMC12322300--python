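# Methods

## Scope and data model

The pipeline starts from a normalized protein × sample quantity matrix
(positive intensities, explicit missing cells), per-protein identification
metadata (identification P value, per-cell peptide counts), a sample
design table (patient, excision/lesion pair, tissue ∈ {cNF, skin}, growth
status), and GO annotations (GAF 2.2 or a protein→term TSV) restricted to
the proteins present. Upstream steps — acquisition, spectral-library
search, and the vendor normalization — are out of scope; quantities are
assumed comparable across samples on arrival. An optional
`median_normalize` is provided for data that are not.

Protein identifiers are opaque strings; the GO join key is whatever
identifier type the quantity matrix uses (column 2 of the GAF). GO graph
up-propagation is not performed: annotations are used as listed, since
term-level modeling treats each term's listed protein set as its
definition. Missing cells are empty TSV fields, never 0 — zero is not a
valid intensity and must never silently become one.

## Confidence filter

A protein is retained iff its identification P value is strictly below
0.05 and it has at least two peptides in at least one sample. Both
thresholds are configurable; comparisons are strict (`P = 0.05` is
dropped). The filter is idempotent and never touches quantities.

## Missingness classification and imputation

A missing value is informative when the protein is evidently expressed in
one tissue but undetectable in the other. Concretely, allowing up to 20%
of observations to be missing at random: if a protein is quantified in
≥80% of the samples of one tissue, detection is considered reliable, and
missing values in excess of 20% in the *other* tissue are attributed to
expression below the limit of detection and imputed with the single
minimum quantity observed in the dataset. If the protein is detected in
<80% of samples in both tissues, nothing is imputed.

Numerical choices:

- Detection fractions are exact rationals (`fractions.Fraction`), so the
  boundary case 12/15 detected (missing exactly 20%, not "in excess of")
  is decided without floating-point error. Reliability is `>= 4/5`,
  excess is `> 1/5`.
- "Missing values in excess of 20%" is read as: once the threshold is
  exceeded, *all* of the protein's missing cells in that tissue are
  imputed (`imputation.mode: all`, the default). Individual missing cells
  are exchangeable, so imputing only the count above the allowance would
  require an arbitrary cell choice; that variant is nevertheless
  implemented (`mode: excess`, taking cells in sample order) for
  sensitivity analysis.
- Detection fractions are computed per tissue across all patients, not
  per donor: pools of 3–5 samples per donor cannot resolve an 80%
  threshold.
- The dataset minimum is taken over the confidence-filtered matrix,
  before imputation; the ordering is recorded in the run report.
- Observed cells are never modified; the operation is idempotent.

Remaining missing values are treated as missing at random and excluded
row-wise from all model likelihoods (standard likelihood treatment);
imputed below-LOD values participate as ordinary observations.

## GO roll-up and mixed models

Terms with more than four distinct proteins in the dataset are eligible.
A term's observation table has one row per (member protein, sample) with
a non-missing quantity, log-transformed with the natural log (the base
cancels after exponentiating the tissue coefficient).

The GO-term model regresses log quantity on a tissue indicator
(cNF = 1, skin = 0) with random intercepts for protein, patient, and
excision nested within patient. "Excision" (the lesion pair) is the
default nesting unit because it encodes the cNF/skin matching; a
specimen-level alternative (`sample_unit: specimen`) is provided, since
with several proteins per specimen it is also estimable. Estimation is
REML via statsmodels MixedLM, expressing the crossed protein intercept
and the nested patient/excision intercepts as variance components over a
single trivial grouping factor. Inference on the tissue coefficient is
Wald-type with normal critical values: `ratio = exp(b)`,
`CI = exp(b ± 1.96·SE)`, two-sided P from the z statistic. Small-sample
df corrections (Satterthwaite-style) would widen CIs slightly; the choice
is recorded in output metadata and its effect is visible in the
simulation coverage estimates below.

Non-convergence triggers a fixed simplification cascade: full →
no-patient-intercept → protein-intercept-only (for single-protein models:
patient/excision → excision → ordinary least squares). Convergence means
the optimizer returned finite estimates with a finite positive standard
error; boundary ("singular", zero-variance) fits count as converged. The
cascade is deterministic and testable through an injectable failure hook.
The structure actually used is recorded per estimate.

Bonferroni correction multiplies each P by the family size and caps at 1.
The default family is the number of terms actually tested in the run,
overridable by config.

Sensitivity analyses re-run any analysis on a lesion subset (all lesions
of one patient, or lesions reported as growing), always keeping both
members of each retained pair.

## GO indices and correlations

The per-sample index of a term is the arithmetic mean over the term's
proteins of the protein's quantity divided by its average over *all*
samples — both tissues, even when the correlation is later restricted to
one tissue (literal construction; protein means over a tissue subset
would re-center the index per tissue and absorb part of the tissue
effect). The index is scale-invariant, and for complete data each
protein's normalized mean is exactly 1. Samples missing some term
proteins use the mean of the available normalized values, with the count
reported for audit. Correlations regress log response index on log
predictor index within one tissue with a patient random intercept; the
response/predictor orientation is an explicit argument. If the mixed fit
is degenerate (e.g. perfectly collinear indices), plain regression
supplies the limiting Wald test. No multiplicity correction is applied to
correlation panels.

## Clustering

Samples are clustered agglomeratively with complete linkage on Euclidean
distances over complete-case (no remaining missing value), log-scale,
optionally per-protein z-scored profiles; z-scoring is the default so
high-abundance proteins do not dominate. Metric and scaling are
config-exposed and recorded, as only the linkage rule is fixed by the
method. Complete linkage guarantees monotone merge heights, asserted on
every tree. Ties in the minimum inter-cluster distance are resolved by
scipy's nearest-neighbor-chain implementation; on continuous data ties
have measure zero. Both pooled and per-donor clustering are provided, and
a two-cluster tissue-purity score in [0.5, 1] summarizes tumor/skin
separation.

## Synthetic data generator

`simulate_study` draws from the same generative structure the models
assume: per-protein baseline `mu_p = m_g + delta_p` with term-level means
`m_g ~ N(18, 1.5²)` (ln-intensity units, i.e. typical normalized DIA
intensities of ~10⁷–10⁸) and within-term protein intercepts
`delta_p ~ N(0, 0.5²)`; patient effects SD 0.15; excision effects SD 0.2;
residual SD 0.35; per-term log tissue effects spanning the ratio range
0.4×–2.1× by default. Censoring applies to the full realized log quantity
(not the protein mean alone), mirroring a detection limit acting on
measured intensity: cells with `log q < lod` (default 13.9) become
missing with cause `censored_lod`; surviving cells drop out completely at
random at rate 0.02 (`dropout_mar`). Ground truth records every cause,
effect and draw. The default design is 4 patients with 3, 4, 4, 4 lesion
pairs (15 pairs, 30 samples) and 20 terms × 10 proteins plus 50
unannotated background proteins; the two largest donors carry the
presumed-growing lesions (8 of 15). Variance-component magnitudes are not
reported for the real cohort, so the defaults were chosen once to give
single-study CI widths comparable to the published effect tables and are
recorded in `truth.json` rather than claimed to match the study.

A single RNG stream seeded from the config is consumed in a fixed order
(term effects → term means → protein intercepts → patient → excision →
residuals → MAR mask → identification metadata), making outputs
bit-reproducible; the committed fixture is `fixture_small()` (seed
20210702). Identification metadata are generated so every protein with at
least one observed cell passes the default confidence filter;
`n_contaminants` adds proteins that deliberately fail it (alternating
high identification P and single-peptide support).

What the generator does not emulate: peptide-level variation and shared
peptides, correlated proteins within a term beyond the shared term mean,
abundance-dependent technical variance, batch effects, or real GO
topology. Passing tests therefore demonstrate correctness of the
algorithms and calibration under the assumed model, not robustness to
violations of it.

## Operating characteristics

`cnfprot.evaluation.recovery_experiment` re-estimates known tissue ratios
{0.4, 0.6, 1.0, 1.5, 2.1} over replicate simulated studies at the
4-patient/15-pair design with 8 proteins per term (one term per ratio,
censoring and dropout disabled so recovery isolates the model). The
acceptance suite asserts |median log-ratio bias| ≤ 0.02, CI coverage
within [0.90, 0.99], and null type-I error within binomial bounds of
0.05 at 200 replicates; `scripts/acceptance.py` recomputes the same
quantities plus QC counts, censored-label recall, GO-index checks and
clustering purity from a user-supplied seed. Problem sizes (200
replicates, 8 proteins/term, 500 oracle matrices, ≤12-sample clustering
oracles) were chosen to keep the full suite and the acceptance script in
the low minutes on one CPU while leaving Monte-Carlo error well inside
the asserted bands.

## Known limitations

- Wald/normal inference slightly undercovers relative to Satterthwaite
  t-intervals in very small subsets (e.g. single-patient sensitivity
  analyses); observed coverage at the default design is ~0.93–0.96.
- The MixedLM variance-component emulation of crossed random effects
  scales quadratically in dummy columns; it is comfortable at hundreds
  of observations per term but would need a sparse backend for terms
  with many hundreds of proteins.
- Only the dataset-minimum imputation rule is implemented; model-based
  imputation (kNN, MinProb, maximum likelihood) is out of scope.
- GO enrichment testing (membership statistics) is deliberately absent:
  the method models quantities, not membership.
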