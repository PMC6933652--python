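# Methods

## Model and procedure

`purityboost` treats tumor purity prediction as bounded-response regression.
Observed purities live in [0, 1]; boosted-tree regressors with a
least-squares loss are unconstrained, so the target is the logit
`z = ln(y / (1 − y))` and predictions return through the inverse logit,
which keeps every prediction strictly inside (0, 1).  Boundary purities are
reassigned to fixed interior constants before the transform: 1.00 → 0.9975
and, symmetrically, 0.00 → 0.0025.  The upper constant is treated as a fixed
property of the method rather than recomputed from each dataset (it
originated as the midpoint between the two largest purity values in the
cohort the method was developed on); keeping it fixed makes results
reproducible regardless of input data.  Values beyond the constants are
clamped to them, so the logit is always finite.

Expression preprocessing floors normalized counts at 1 before log2 (so the
log2 scale has a hard zero floor), drops genes with missing values or zero
variance, and keeps one sample per patient (lexicographically smallest
sample ID — the retention rule is arbitrary but deterministic).

The predictor is an ensemble of ensembles.  The training set is cut into
R repetitions × k folds (default 100 × 10).  Each repetition independently
shuffles the training samples with a seed derived from the master seed and
splits the shuffled order into k contiguous blocks whose sizes differ by at
most one.  For each of the R·k partitions one XGBoost model is fit on the
(k−1)/k share and early-stopped on the held-out fold.  The final prediction
is the arithmetic mean over models of the inverse-logit per-model outputs.
Averaging could equally be done on the logit scale before the inverse
transform; both orders keep predictions in (0, 1) and the original-scale
average is the default, with `avg_scale="logit"` available.  Repeating the
partitioning many times serves two purposes: bagging the predictions, and
stabilizing the gene ranking against the randomness of per-tree feature
subsampling.

## Learner parameters

Defaults in `GBMConfig` (all overridable):

| parameter | default | meaning |
|---|---|---|
| `learning_rate` | 0.05 | shrinkage per boosting step |
| `max_depth` | 4 | maximum tree depth |
| `min_leaf_weight` | 1 | minimum hessian weight per leaf |
| `colsample_per_tree` | 0.65 | fraction of genes drawn per tree |
| `subsample_per_tree` | 0.85 | fraction of samples drawn per tree |
| `max_trees` | 5000 | boosting-round ceiling |
| `early_stop_patience` | 5 | non-improving rounds before stopping |
| `max_bin` | 32 | histogram bins per feature for split finding |

The first seven are the tuned pan-cancer parameter set the default
configuration reproduces.  Early stopping is monitored on the held-out
validation fold of each partition: with a least-squares loss, training error
essentially always improves, so a patience of five rounds is only meaningful
against held-out error.  A `monitor="train"` flag preserves the alternative
reading.  `max_bin` is an implementation choice of this package: log2
expression values are smooth, and 32-bin histograms give accuracy
indistinguishable from finer binning at a fraction of the single-threaded
cost.

`grid_search` selects the configuration with the lowest mean k-fold CV RMSE
(computed on the original purity scale after inverse logit); ties break
toward the smaller `learning_rate × max_trees` product, then smaller depth,
then grid order.  The packaged default grid is a small 24-point neighborhood
of the default set; the original tuning swept a far larger grid, which is
out of scope here.  Restricting to a gene panel re-runs the grid search on
the panel before retraining, since a 10–20-gene feature space generally
prefers different settings than a 17 000-gene one.

## Seeds and determinism

A single master seed drives everything: repetition shuffle seeds and
per-model learner seeds are derived with `numpy`'s seed-sequence mechanism
from (master, repetition) and (master, repetition, fold) tuples, so models
are independent yet reproducible, and a re-run with the same master seed on
the same machine produces bitwise-identical predictions and importance
files (trainers are fixed to one thread).

## Importance and marker panels

Within one model the importance of gene g is the total split gain (loss
improvement summed over every split on g in every tree, which inherently
weights each split by the observations it covers) divided by the grand
total over all genes — nonnegative shares summing to one per model.  Genes
are ranked within each model by descending score with tied scores sharing
their average rank; the zero-score block therefore shares the bottom rank.
Only genes with positive score in *every* model are eligible for the final
list — a stability filter that removes genes whose usefulness depends on a
particular partition.  Eligible genes are ordered by median within-model
rank (ties: higher mean score, then symbol).  Median-of-scores and
mean-of-scores orderings are implemented as options because the two
aggregation conventions circulate interchangeably; at high signal all three
agree on the top of the list (asserted in the test suite), so the choice
matters only in the low-signal tail.

## Permutation test

The null hypothesis is that expression carries no information about purity.
Training labels are permuted uniformly; the full reduced-scale pipeline
(plan, training, bagged prediction) is re-run per permutation; the test-set
Pearson r (or negative RMSE) is the statistic; test labels are never
permuted.  The reported p-value is the add-one estimate
`(1 + #{null ≥ observed}) / (B + 1)`, which can never be zero and does not
overstate significance at small B.  The exact permutation scheme behind the
original analysis was not published in detail; response-permutation with
full retraining is the standard construction for "could this performance
arise by chance".

## Pseudo-bulk bridge

Pseudo-bulk profiles are per-sample, per-gene sums of raw single-cell
counts.  Harmonization with a reference bulk cohort merges on the exact
common gene symbols, rescales every sample *i* by `c / median_i` where `c`
is the median of the reference samples' medians (even-count medians are
midpoints), and applies `log2(count + 1)`.  The wording "centered on the
median of those medians" admits an additive reading too; multiplicative
rescaling is the default because counts are nonnegative and an additive
shift of raw counts can produce negatives, and an additive-on-log-scale
variant is available behind the `mode` flag.  Both maps are monotone within
a sample, so within-sample gene ranking is unaffected.  Samples whose
median expression is zero (possible for very sparse single-cell data) are
an error for the multiplicative variant rather than a silent division by
zero.

## Synthetic data generator

`simulate_bulk` emulates what makes purity learnable from bulk expression:
tumor samples are mixtures of cancer and stroma, and stromal genes rise as
purity falls.  Purity is Beta(2, 2) (broad, interior-supported), gene
baselines are Uniform(2, 10) on the log2 scale, a random minority of
"stromal" marker genes get an additive `effect_size · (1 − purity)` term,
every gene receives a per-tumor-type batch shift N(0, `type_shift_sd`) and
i.i.d. noise N(0, `noise_sd`).  Defaults — 600 samples, 2000 genes, 20
markers, effect size 2 (log2 units), noise SD 0.5, 3 types with shift SD
0.5 — are the reduced-scale study conditions used throughout the tests: an
effect of 2 log2 units (4-fold) against 0.5 SD noise is a strong but
realistic stromal signature, and type shifts of the same magnitude as the
noise give the batch structure real cohorts have.  The signal is additive
on the log2 scale rather than a count-scale mixture; this keeps the
marker–purity relationship exactly monotone and interpretable, while the
count-scale mixture path is exercised separately through `simulate_cells`
plus pseudo-bulk aggregation.  What the generator deliberately omits:
dropout and overdispersion of real scRNA-seq, copy-number structure,
correlated gene modules, and nonlinear purity responses.  Passing tests
therefore demonstrate that the machinery recovers a planted monotone signal
under batch structure and noise — not that real-tumor accuracy is
guaranteed.

`simulate_cells` draws each cell's identity Bernoulli(purity) and its
counts Poisson(rate profile of its identity); the *realized* cancer-cell
fraction is the recorded ground truth, exactly as cell-type annotation
defines purity in real single-cell cohorts.

## Problem sizes in the tests and acceptance script

The test suite and `scripts/acceptance.py` run the study at reduced scale,
chosen to preserve the statistical behaviour while keeping runs desk-sized:
recovery runs use 600 × 2000 with a 10 × 5 plan and ≤ 300 trees (50 models
instead of 1000); permutation calibration uses 150 × 500 cohorts with a
1 × 3 plan, ≤ 60 trees and B = 19; the pseudo-bulk bridge trains on 120
reference samples of 300 genes and predicts 12 samples of 2000 cells each.
The bagged-prediction RMSE stabilizes well below these ensemble sizes, so
the reduction mainly costs variance in the importance tail, not in the
prediction metrics.

## Known limitations

- Purity labels are taken as given; label error (e.g. from the copy-number
  method that produced them) propagates into the regression target.
- The eligibility rule (non-zero in all M models) becomes very strict as M
  grows with aggressive column subsampling and few informative genes.
- The permutation test re-trains the full pipeline B times; at full scale
  that is expensive, which is why the reduced plan is a parameter.
- Cross-cohort prediction assumes the median-of-medians rescaling removes
  the dominant depth/platform effect; it does not correct gene-specific
  batch effects.
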