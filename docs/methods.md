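# Methods

## Model

Each omics layer is a samples × features matrix.  The encoders apply
single-block self-attention **across the samples of a batch**: with
`Q = XW_Q`, `K = XW_K`, `V = XW_V`, the embedding is
`H = softmax(QKᵀ/√d_H) V`, so QKᵀ is n × n and every sample's embedding
is a convex combination of the value rows of its batch — a learned,
kernel-like smoothing over similar samples.  Per-layer embeddings
(default width 64) are concatenated and fused by one more attention
block to a fixed width (default 32); an affine softmax head yields class
probabilities; affine decoders map each `H^(i)` back to its input space.
There is no positional encoding (samples are unordered), no masking and
no multi-head splitting; one attention block per layer plus one fusion
block.  Score scaling uses the standard `√d` convention; a literal `/d`
variant is selectable (`scale_mode="linear"`).

Because the printed attention formulas for this family are sometimes
typeset without the radical, the package treats `√d` as the default and
documents the switch rather than guessing silently.

### Batch context at inference

A consequence of attending across samples is that an embedding depends
on the batch it is computed in.  A query batch embedded alone lacks the
training cohort's context, and we found empirically that a trained model
scores an isolated held-out batch near chance while the same samples
embedded jointly with the training batch are classified almost
perfectly.  The fitted model therefore stores its training batch and all
prediction (`predict_proba`, `evaluate`, `RiskModel.encode`,
`assign_risk`) embeds queries jointly with that stored reference,
reading off the query rows — transductive scoring in the spirit of
nearest-neighbour methods.  Attention is permutation-equivariant and
invariant to duplicated rows, so each query's output does not depend on
the order or presence of other queries' duplicates; it does depend
mildly on which other queries share the call, which we accept and note
here.

## Two-phase training

Phase 1 minimizes the summed squared-Frobenius reconstruction error over
all layers; phase 2 minimizes `L = L_re + a·L_Cross` jointly.  The
classification term defaults to mean cross-entropy of the softmax head
(probabilities clamped at 1e-12); a literal squared-probability variant
`mean_p Σ_c (1[y_p=c] − P_pc)²` is selectable because the loss is
sometimes written in that form.

Optimization is full-batch Adam (lr 1e-3) — the cohorts this package
targets (n ≈ 160) make mini-batching unnecessary and full batches keep
every forward pass deterministic.  Defaults: 100 pretraining epochs and
40 finetuning epochs.  Finetuning anneals the learning rate to zero on a
cosine schedule over its configured epochs, so the refinement phase has
converged by its end (the joint loss changes by <1% between epochs 40
and 60 when run for 60); a constant schedule is available.  No early
stopping: the final-epoch model is returned.  Gradients are explicit
NumPy backpropagation verified against central finite differences in the
test suite; weights initialize from a seeded scaled normal
(std = 1/√d_in).

The train/test split is stratified 80/20 by seeded draw.  Evaluation
reports ACC, macro-F1 (unweighted mean of per-class F1) and Purity
(majority-class mass of predicted groups).  Multi-seed experiments
report means over 10 seeds.

## Preprocessing

Fixed order: **filter → impute → log2 → center/scale**.

* Protein layers keep features with CV < 0.3 (sample sd / mean over
  non-missing raw values) **and** missing fraction < 0.25; other layers
  keep features with missing fraction < 0.20, so every retained missing
  cell is eligible for the single imputation rule.  All comparisons are
  strict.
* Missing cells (and non-positive observed values) are imputed as
  `factor ×` the layer's minimum positive observed value.  The default
  factor 1/83 is a detection-limit style rule meant for raw-scale
  abundances spanning orders of magnitude.  For data already on a log
  scale the appropriate member of the same family is the observed
  minimum itself (`impute_factor=1.0`, standard minimum-value
  imputation) — imputing a log-scale matrix at a small fraction of its
  minimum plants extreme low outliers that corrupt both standardization
  and sample-similarity structure.
* Designated layers are log2-transformed; then every feature is centered
  and scaled to unit variance with training statistics (constant
  features are removed first).  Blood panels get center/scale only — no
  CV filter, no log2 — because clinical analytes include values for
  which a log transform is inappropriate.

## Blood-panel risk model

Latent dimension 8 for the 25-parameter panel; autoencoder trained 300
epochs.  Clustering is k-means (k default 3) with 50 seeded restarts
keeping the lowest inertia.  Centroids are within-cluster means of the
latent embeddings.  Risk levels order clusters by the mean of their
decoded, standardized panel values — the high-risk group is the one
whose blood indices run largest overall; this magnitude proxy is
overridable by explicit configuration, and exact ties break by cluster
index.  Assignment ties break toward the lower risk level (conservative
labeling; determinism matters more than direction).  Missing panel
fields in new records are imputed with stored training medians, with a
per-record warning.

## Trajectory analysis

Records are binned by years-to-onset into half-open, left-closed bins
`[a, b)`; records dated after onset are excluded with a warning, records
beyond the last edge dropped with a count.  All records in one call are
risk-assigned as a single batch, so the table is invariant to input
order.  Multiple records per patient all count (record-level
proportions); the trend is the least-squares slope of the high-risk
proportion against the negated bin midpoint — a deliberately plain
summary rather than a named test, since the quantity of interest is the
sign and rough size of the drift.

## Synthetic generators

`generate_multiomics_cohort` emulates a 160-sample cohort in three
groups of 80/41/39 across four layers (2000/800/400/300 features —
desk-scale stand-ins for full assay widths; the method is
dimension-agnostic).  Background features are Gaussian around a positive
baseline (12 ± 1 by default) — the shape abundance data takes *after*
log transformation, which is why the matched recipe
(`synthetic.cohort_recipe`) applies no second log2 and uses
minimum-value imputation.  Each informative feature (default 40 per
layer, roughly the differential fraction expected between distinct
physiological groups at this scale) shifts group means by ±δ·sd
(default δ = 1.5) according to per-group ±1 sign patterns; patterns are
redrawn until no feature is constant across groups and every pair of
groups differs on at least half the informative features, which
guarantees identifiability (with a single ±1 feature and three groups
full pairwise separation is impossible, so only non-constancy is
enforced there).  Entries go missing completely at random (default 5%).

`generate_blood_panel` draws a 25-column Gaussian mixture whose k group
means are equally spaced along the all-ones direction with adjacent
pairs `separation` within-group sds apart (with three collinear means
encoding increasing magnitude, all three pairwise distances cannot be
equal — the adjacent-pair convention is documented here).  Group index
increases with overall magnitude, so the planted risk ordering is
recoverable.

`generate_longitudinal` gives each patient dated records over a 5-year
pre-onset history (2 per year, 100 patients by default); a record at
time-to-onset t is drawn from the high-risk mixture component with
probability `exp(−t/τ)` (τ default 3 years), with centroids matching
the panel generator's lowest and highest groups.

What the generators do **not** emulate: realistic RNA count
distributions, assay-specific noise, batch effects, feature-feature
correlation beyond the planted group structure, informative missingness
(real omics missingness is largely detection-limit censoring), or any
correspondence between synthetic risk levels and real disease risk.
Passing tests therefore demonstrate correct mechanics and recoverability
of planted structure at realistic sizes — not clinical performance.

## Experiment designs used by the tests and acceptance script

* Classifier recovery: the default cohort (δ = 1.5, 5% missing), 10
  seeds; the null repeats it with δ = 0.  With unbalanced groups a
  cross-entropy-trained head legitimately drifts from uniform chance
  (1/3) toward the majority rate (0.5) by learning the label prior, so
  the null check uses the binomial band of one test split, which
  tolerates prior learning while catching genuine leakage.
* Importance recovery: two layers of 110 features with 5 planted each at
  δ = 3 (a deliberately strong effect, complete data), 300/100 epochs so
  the baseline fit is adequate at this reduced width; 10 whole-scan
  repetitions of 10 runs each.  Ablation zeroes the feature column in
  both the evaluation batch and the stored training reference, so the
  forward pass sees the feature nowhere.
* Blood-panel recovery and trajectory: default generator settings
  (separation 6, τ = 3y), 10 seeds.

Problem sizes were chosen so the full suite runs in minutes on a single
CPU while keeping every cohort at the sizes stated above.

## Numerical choices and degenerate inputs

Softmax is computed with row-max subtraction; cross-entropy clamps
probabilities at 1e-12; CV requires ≥2 observed values and non-zero
mean; scaling requires strictly positive feature sds; attention tie
cases (all-zero input) reduce to exact uniform weights; non-finite
training losses abort with diagnostics, and importance-scan runs that
diverge are retried once with an offset seed.  Model files are single
`.npz` archives with an embedded JSON header carrying a format version;
loading any other version fails explicitly.

## Known limitations

* Transductive scoring means a prediction depends on the stored training
  batch; two models trained on different cohorts will embed the same
  record differently.
* Attention across samples underperforms at very small n (a few dozen
  samples), where the batch context carries little signal.
* The importance scan is O(features × forward pass) per run and is
  intended for the post-selection widths used here, not for full
  transcriptome-scale ablation.
* The risk-level ordering proxy (decoded panel magnitude) encodes the
  assumption that higher overall blood indices mark higher risk; cohorts
  where risk manifests differently need the explicit override.
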