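# Methods

## Problem setting

Clinical variant interpretation needs a single pathogenicity score that
works for SNVs and InDels across molecular consequences and, critically,
for rare and ultra-rare variants where most specialised predictors degrade.
varboost implements the full training-and-benchmarking protocol for such a
score as a library and CLI: the supervised signal comes from curated
databases of labelled variants of uneven trustworthiness, the features
from a fixed 92-annotation table plus population allele frequency, and the
classifier is a sample-weighted gradient-boosted tree ensemble.

## Curation model

Merging is keyed on the allele-level identity (chrom, pos, ref, alt),
1-based, VCF-convention, multi-allelic records split per alt. Position-only
identity would collapse distinct alleles at one site, so it is not used.
Inputs are assumed left-normalized; no re-normalization is performed
because silent normalization would change deduplication behaviour.

Keys labelled both pathogenic and neutral across sources are removed
entirely — a conflicting label is evidence of curation disagreement, not a
majority vote. Same-label duplicates keep the record from the
highest-priority source (configurable order; default: order of appearance).
The audit tracks both removed keys and removed records so the accounting
identity `rows_in = rows_out + duplicates_removed + conflict_records_removed`
holds exactly and is asserted in tests.

The dominant-gene filter removes variants *only* from general-population
sources: healthy cohorts contain unaffected carriers of
dominant-inheritance disease variants, so their presence in a cohort is not
evidence of neutrality. Curated-source variants are never touched. The
dominant-term vocabulary defaults to {AD, XLD, "autosomal dominant",
"x-linked dominant"}, matched case-insensitively against whole modes or
`/ , ;`-separated tokens (so `AD/AR` counts as dominant); genes missing
from the inheritance table count as non-dominant and are tallied.

Confidence tiers: a ClinVar-style source is high-confidence at
"criteria provided, multiple submitters, no conflicts", "reviewed by expert
panel" or "practice guideline"; a lab-consortium source is high-confidence
with at least one supporting lab and no conflicting interpretation.
Weights default to 1.0 (high) and 0.8 (low); 0 ≤ low ≤ high ≤ 1 is
enforced. Weight 0 is implemented by removing the rows before fitting, so
the equivalence with exclusion is exact by construction and asserted
bit-level in tests.

The benchmark takes a seeded 50% split (round-half-to-even) of the
high-confidence pathogenic variants, then draws neutral variants per
consequence to equal counts (n_c = min(available pathogenic, available
neutral)) with allele-frequency matching: the neutral draw follows the
pathogenic AF-bin histogram with per-bin quotas over the default edges
{0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1}; a bin short of neutral
variants is refilled from adjacent bins outward (lower neighbour first),
and all shortfalls/refills are reported. Consequences with an empty
neutral pool are excluded and logged. Training and benchmark are disjoint
by key after every run.

Population-cohort neutral sets take quality-passing variants (PASS read
from the VCF FILTER field, per the 4.x standard) with within-cohort
AF < 1% that are unseen in training.

## Feature encoding

Each of the 11 categorical features retains its ≤5 most frequent training
levels (ties broken lexicographically) and expands to one indicator per
retained level plus an explicit `other` indicator (observed, unretained
level) and `missing` indicator (absent value). Explicit indicators rather
than all-zero rows keep the transform information-preserving: the encoded
matrix distinguishes "rare level" from "no annotation". The 81 numerical
features pass through with fixed-value imputation — an externally
recommended imputation table can be supplied as overrides; the default is
the training median, which is well-defined on any fitted schema. The
population AF joins as a final column, 0 for variants absent from the
lookup (absence from a large population database is itself evidence of
rarity). Column count is therefore
Σ_categorical (retained + 2) + 81 + 1, asserted per schema. The fitted
schema serializes to JSON; transform-time encoding is schema-driven only,
so disjoint datasets always encode to identical column sets.

## Model and training

XGBoost (`binary:logistic`, `hist`, single-thread for bit-reproducibility)
minimizes the sample-weighted logistic loss. Randomized search samples
hyperparameter tuples uniformly (n_estimators, max_depth integer ranges;
learning-rate choices) with a seeded generator and scores each by mean
validation AUC over stratified K folds (default 5), fitting each fold with
sample weights and early stopping (default 15 rounds) on the fold's
validation half. Stratification is used because degenerate single-class
folds are a real risk at test scale; such folds are skipped with a
warning. The final model is refit on the full training set at the winning
tuple without early stopping — the refit protocol is this package's
choice.

Default parameters for desk-scale runs are learning_rate 0.1, max_depth 3,
n_estimators 200: a shallower, smaller analogue of the optimum found by
the full search on production-scale data (0.1 / 15 / 422), appropriate for
the 10³–10⁴-row synthetic sets used here where deep trees overfit the
noise features.

## Threshold selection

The decision threshold is selected on training scores: scan the ascending
grid {0, s, 2s, …, 1} (default step s = 0.001; the published protocol
scans "all" thresholds without stating a step) and return the first t with
recall(t) = P(score ≥ t | pathogenic) inside [0.94, 0.96]. Ties at the
threshold count as detected (≥), which keeps recall(0) = 1. If no grid
point attains the band (e.g. perfectly separated scores jump from recall
1.0 to below 0.94), the default fallback returns the grid point whose
recall is closest to the band midpoint, smallest t on ties, flagged
`in_band=False`; an `error` fallback is available. The published operating
point 0.02 for pre-trained score files is kept only as a documented
reference constant and never influences selection.

## Evaluation

AUC is computed by the midrank Mann–Whitney formula
(R⁺ − n⁺(n⁺+1)/2) / (n⁺ n⁻), which equals the all-pairs mean of
{1, ½, 0} exactly, including ties; tests verify exact (1e-12) agreement
with a brute-force oracle and cross-check against scikit-learn. The
bootstrap SD uses 100 resamples with replacement at the original size
(population SD); single-class resamples are redrawn up to 10 times, then
skipped with a warning.

Confusion matrices accept absent scores (tools that return no prediction)
and tally them per true class, preserving the identities
tp+fn+no_pred⁺ = n⁺ and tn+fp+no_pred⁻ = n⁻. Two false-positive rates are
kept deliberately: `ConfusionSummary.fpr` = fp/(fp+tn) over predicted rows
(the conventional definition), and `false_positive_rate` = fp/(all true
neutral) including missing predictions — the definition appropriate when
comparing tools with different prediction coverage. Reports state which is
shown.

Stratified evaluation defaults to five AF bins — {0}, (0, 1e-4],
(1e-4, 1e-3], (1e-3, 1e-2], (1e-2, 1] — exact zero being its own bin
because "absent from the population database" is a qualitatively distinct
state. Bin edges are configuration, not an inference about any published
figure. Strata missing a class are reported as not-evaluable with counts.

## Exome ranking

Variants with AF strictly above the cutoff (default 10%; the boundary
value is retained) are removed; a causal variant removed by the filter or
absent from the patient's list raises an explicit error rather than a
silent miss. Remaining variants sort by score descending; the causal
variant's rank is the *worst* position within its score-tie group — a
conservative choice for the evaluated tool — and unscored variants form a
bottom tie group. Top-percent yield is boundary-inclusive
(percentile ≤ percent) and is reported both per case (a case with several
causal variants counts once, via its best-ranked one) and per variant.

## Synthetic data

The generator emulates the pipeline's inputs, not biology. Defaults, each
chosen once:

- **Signal**: one informative numerical feature, Normal(d, 1) vs
  Normal(0, 1), d ≥ 0 configurable (default 1). A single informative
  feature keeps the Bayes AUC closed-form, Φ(d/√2), verified in tests
  against numerical integration; multi-feature signal has no such oracle
  and is out of scope for the default configuration.
- **Noise**: 80 further numerical features ~ Normal(0, 1) in both classes;
  11 categorical features with six levels at identical class-conditional
  probabilities (0.30/0.25/0.20/0.15/0.07/0.03 — six levels so the
  top-5 retention rule is exercised).
- **Allele frequency**: a mixture of a point mass at 0 (p = 0.35,
  "absent from the population database") and a log-uniform tail on
  [1e-6, 1e-2], *identical in both classes* so AF carries no class signal
  and the Φ(d/√2) oracle stays exact. Class-specific AF models are
  available by configuration.
- **Consequence mix**: pathogenic enriched for missense/stop-gained/
  frameshift/canonical-splice, neutral for synonymous/non-coding, roughly
  reflecting curated-vs-population composition. Consequence is metadata
  (used by balancing, stratification and ranking), never a model feature.
- **Confidence**: 90% of curated-source variants are low-confidence,
  mirroring the roughly 9:1 low:high ratio typical of merged curated
  training sets; half of neutral variants come from a population source.
- **Missingness**: each annotation cell is independently absent with
  probability 0.05.
- Keys are unique by construction (sequential positions); all tables
  round-trip through the package readers byte-identically, with zero
  rejects, under a fixed seed.

What the generator does **not** emulate: correlation between annotation
features, linkage between nearby variants, gene-level clustering of
pathogenic variants, realistic AF spectra (no demography), and
label noise that is correlated with the features. Passing tests therefore
demonstrate that the machinery is correct and recovers a known planted
signal — not that the trained model would reach any particular performance
on real annotation data.

Simulated patient cases place one causal variant per patient at a chosen
quantile of the patient's background score distribution (strictly above
all background scores at quantile 1, strictly below at 0), with background
AFs uniform on [0, 0.5] so the 10% AF prefilter is exercised.

## Numerical choices and degenerate inputs

- Threshold grids are built from integer multiples of the step and rounded
  to 12 decimals to avoid floating-point drift; 1.0 is always included.
- The 50% benchmark split size uses round-half-to-even.
- Matrix TSVs are written at %.17g and read with round-trip float parsing,
  making write→read bit-exact.
- XGBoost runs single-threaded with fixed `random_state`, so identical
  configs give byte-identical score files (asserted end-to-end).
- Empty matrices score to empty arrays; single-class training, thresholding
  without pathogenic rows, FPR without neutral rows, and empty rank-result
  sets raise errors naming the problem.

## Problem sizes

Default test and acceptance computations use 10,000-variant training sets
(threshold contract, d = 1.5), 4,000/2,000 train/test (Bayes-AUC recovery,
d = 1), a 1,000-variant pool for benchmark balancing, and 20 patients ×
1,000 variants for ranking — sizes at which every documented statistical
check is stable under its stated tolerance while the whole suite runs in
well under a minute.

## Known limitations

- The identities of the real 92 annotation features and the externally
  recommended imputation values are deliberately external: the feature
  manifest and imputation-override table are the extension points.
- The randomized search reproduces uniform-sampling semantics but not any
  specific historical library's draw sequence.
- Bootstrap SD is a dispersion estimate, not a confidence interval; no
  AUC-comparison tests (DeLong etc.) are provided.
- Scores are raw classifier outputs; no probability calibration is
  performed beyond the logistic link.
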