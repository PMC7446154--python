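# varboost

Gradient-boosted pathogenicity scoring for genomic variants, built for the
kind of study where a classifier must be trained on heterogeneous curated
databases (ClinVar/VKGL-style exports plus population cohorts) and then
evaluated without bias across molecular consequences and allele-frequency
ranges. The package implements the full protocol — curation, feature
encoding, confidence-weighted training, recall-constrained thresholding,
stratified evaluation and clinical exome ranking — and ships a synthetic
variant generator with a known Bayes-optimal AUC so every stage can be
exercised and validated offline.

Intended users: developers and evaluators of variant prioritization
methods who need a reproducible, desk-scale version of this training and
benchmarking protocol.

## The method

**Curation.** Labelled variants from several sources are merged on the
allele-level key (chrom, pos, ref, alt); duplicate records collapse to the
highest-priority source and keys with conflicting labels are dropped
entirely. Variants from general-population cohorts that fall in
dominant-inheritance genes are removed (they are carrier variants, not
evidence of neutrality). Each variant gets a sample weight *w* from its
review status: well-supported records (multi-submitter no-conflict,
expert-panel or practice-guideline ClinVar tiers; lab-consortium records
with ≥1 lab and no conflict) get *w* = 1, the rest *w* = 0.8 (configurable,
including *w* = 0, which is provably identical to excluding the rows).
Half of the high-confidence pathogenic variants are held out and matched
with neutral variants so that, per molecular consequence *c*, the
benchmark contains equal pathogenic/neutral counts with matched
allele-frequency histograms.

**Model.** Features are 11 categorical annotations (one-hot over the ≤5
most frequent training levels, plus explicit *other*/*missing*
indicators), 81 numerical annotations (fixed-value imputation), and the
population allele frequency (0 when unknown). An XGBoost classifier
minimizes the weighted logistic loss

    L = Σ_i w_i · ℓ(y_i, p_i),   p_i = σ(F(x_i)),

with hyperparameters (n_estimators, max_depth, learning_rate) chosen by
seeded randomized search under stratified 5-fold CV with 15-round early
stopping per fold.

**Operating point.** The decision threshold *t* is the first point of the
ascending grid {0, 0.001, …, 1} whose training recall
P(score ≥ t | pathogenic) falls in [0.94, 0.96].

**Evaluation.** AUC is the Mann–Whitney statistic (ties = ½) with a
100-repetition bootstrap SD, reported overall and stratified by AF bin and
consequence; confusion matrices account explicitly for tools that return
no prediction, and the false-positive rate divides by *all* true neutral
variants. For solved exomes, variants with AF > 10% are removed, the rest
are sorted by score, and the causal variant's rank (worst position among
ties) and the cohort top-1% yield are reported.

**Synthetic data.** The generator plants the class signal in a single
numerical feature — Normal(d, 1) for pathogenic vs Normal(0, 1) for
neutral — among class-independent noise features, so the optimal AUC is
the closed form Φ(d/√2) and parameter recovery is testable.

## Worked example

```python
from varboost import (
    SimulationConfig, simulate_dataset, curate, train_model, predict,
    select_threshold, compute_auc, bootstrap_auc_sd, bayes_auc,
)
from varboost.modeling import DEFAULT_PARAMS, ThresholdPolicy
from varboost.preprocessing import attach_labels, encode_features, fit_feature_schema

config = SimulationConfig(n_pathogenic=2000, n_neutral=2000,
                          informative_shift=1.5, seed=7)
dataset = simulate_dataset(config)
curated = curate([dataset.variants], dataset.inheritance, seed=7)
print(f"training variants:  {len(curated.training)}")
print(f"benchmark variants: {len(curated.benchmark)}")

ann = {a.key: a for a in dataset.annotations}
schema = fit_feature_schema([ann[v.key] for v in curated.training], config.manifest)
m_train = attach_labels(
    encode_features([ann[v.key] for v in curated.training], dataset.af_lookup, schema),
    curated.training)
m_bench = attach_labels(
    encode_features([ann[v.key] for v in curated.benchmark], dataset.af_lookup, schema),
    curated.benchmark)

model = train_model(m_train, DEFAULT_PARAMS, seed=7)
th = select_threshold(predict(model, m_train), m_train.labels, ThresholdPolicy())
print(f"decision threshold: {th.threshold:.3f} (training recall {th.recall:.3f})")

scores = predict(model, m_bench)
mean, sd = bootstrap_auc_sd(scores, m_bench.labels, n_reps=100, seed=7)
print(f"benchmark AUC:      {compute_auc(scores, m_bench.labels):.3f} +/- {sd:.3f}")
print(f"Bayes AUC at d=1.5: {bayes_auc(1.5):.3f}")
```

Output:

```
training variants:  3617
benchmark variants: 180
decision threshold: 0.420 (training recall 0.960)
benchmark AUC:      0.889 +/- 0.025
Bayes AUC at d=1.5: 0.856
```

The 4,000 simulated variants shrink to 3,617 training and 180 benchmark
variants after conflict removal, the dominant-gene carrier filter and
per-consequence balancing. The selected threshold hits the top of the
[0.94, 0.96] recall band on the training scores. The held-out benchmark
AUC of 0.889 ± 0.025 is statistically consistent with the closed-form
optimum Φ(1.5/√2) ≈ 0.856 for the planted single-feature signal (the
small benchmark makes the bootstrap SD wide).

The same pipeline runs from the shell — `varboost simulate | curate |
encode | train | threshold | predict | evaluate | rank`, or `varboost run
--config cfg.json --out-dir out/` for the whole chain with a checksum
manifest. Every stage takes explicit seeds.

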