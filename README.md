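# purityboost

Tumor purity — the fraction of a tumor sample's cells that are cancer cells,
the rest being stroma (immune cells, fibroblasts, vasculature) — shapes every
bulk-expression analysis of tumors.  `purityboost` predicts purity directly
from bulk RNA-seq gene expression with an *ensemble of boosted-tree
ensembles*, discovers compact stromal marker-gene panels from the ensemble's
split-gain importance, quantifies significance by label permutation, and
bridges to single-cell data via pseudo-bulk aggregation.  It is written for
computational biologists who have expression matrices and purity labels
(e.g. from a copy-number method such as ABSOLUTE) and want an
expression-only purity predictor or a small marker panel.

## Method

Observed purities `y ∈ [0, 1]` are mapped to the real line by the logit
`z = ln(y / (1 − y))` after reassigning boundary values (1.00 → 0.9975,
0.00 → 0.0025).  Expression values are floored at 1 and log2-transformed;
genes with missing values or zero variance are dropped.

The training set is partitioned by **R repetitions of k-fold
cross-validation** (default 100 × 10): each repetition reshuffles the
samples and cuts them into k contiguous blocks, giving R·k = M
training/validation partitions.  One stochastic gradient-boosted tree
regressor (XGBoost, least-squares loss; learning rate 0.05, depth 4,
minimum leaf weight 1, 65 % of genes and 85 % of samples per tree, ≤ 5000
trees with early stopping after 5 non-improving rounds on the validation
fold) is fit per partition.  The final prediction for a test sample is the
bagging average

```
ŷ = (1/M) Σ_m  logit⁻¹( f_m(x) )
```

Within model *m*, gene importance is the normalized split-gain share
`S_g = (Σ_t S_gt) / (Σ_t Σ_g' S_g't)` over all trees *t*.  A gene is
rankable only if `S_g > 0` in **all** M models; rankable genes are ordered
by their median within-model rank.  The top of that ordering is the marker
panel; a ten-gene panel (*CSF2RB, RHOH, C1S, CCDC69, CCL22, CYTIP, POU2AF1,
FGR, CCL21, IL7R*) ships as `purityboost.TEN_GENE_PANEL`.

Significance is assessed by permuting the training purities B times,
re-running the whole train+predict procedure, and reporting the add-one
empirical p-value `(1 + #{null ≥ observed}) / (B + 1)`.

For single-cell validation, per-sample pseudo-bulk profiles are the
per-gene sums of raw counts over a sample's cells; they are merged with a
reference bulk cohort on common genes, every sample is rescaled to the
median-of-medians of the reference samples, and values are mapped through
`log2(count + 1)`.  Ground-truth purity of a pseudo-bulk sample is its
annotated cancer-cell fraction.

A synthetic admixture generator (`purityboost.simulate_bulk` /
`simulate_cells`) provides data with known purity and planted stromal
marker genes for development and testing.

## Worked example

```python
import purityboost as pb
from purityboost.preprocess import logit_transform, split_train_test

# synthetic cohort: 600 samples x 2000 genes, 20 planted stromal markers
m, purity, truth = pb.simulate_bulk(seed=1)
split = split_train_test(m, purity, fraction=2/3, seed=1)
m_tr, p_tr = m.subset_samples(split.train_ids), purity.subset(split.train_ids)
m_te, p_te = m.subset_samples(split.test_ids), purity.subset(split.test_ids)

plan = pb.build_cv_plan(m_tr.sample_ids, n_repetitions=10, n_folds=5, master_seed=1)
ens = pb.train_ensemble(m_tr, logit_transform(p_tr),
                        pb.GBMConfig(max_trees=300), plan)

res = pb.predict(ens, m_te)                       # bagged test predictions
r, rho = pb.correlations(p_te.values, res.final)
print(f"held-out Pearson r = {r:.3f}, RMSE = {pb.rmse(p_te.values, res.final):.3f}")

table = pb.aggregate_importance(ens.per_model_importance, ens.gene_symbols)
panel = pb.top_k_panel(table, 10)
hits = len(set(table.final_order[:40]) & set(truth.marker_genes))
print(f"planted markers recovered in top-40: {hits}/20")
```

Output:

```
held-out Pearson r = 0.954, RMSE = 0.078
planted markers recovered in top-40: 20/20
```

The bagged predictor explains most of the purity variation on held-out
samples (r ≈ 0.95 at this signal strength), and the importance ranking
places all 20 planted marker genes within the top 40 of 2000 — the
behaviour the marker-discovery procedure relies on.

The same pipeline is available from the shell:

```bash
purityboost simulate --out-dir sim --seed 1
purityboost preprocess --expression sim/bulk_expression.tsv \
    --purity sim/bulk_purity.tsv --scale log2 --seed 1 --out-dir prep
purityboost train --data-dir prep --reps 10 --folds 5 --max-trees 300 \
    --seed 1 --out-dir ens
purityboost predict --ensemble-dir ens --data-dir prep --out pred.tsv
purityboost importance --ensemble-dir ens --out-dir imp
purityboost evaluate --predictions pred.tsv --truth prep/purity.tsv --out eval.json
```

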