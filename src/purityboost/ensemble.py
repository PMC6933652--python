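"""Gradient-boosted tree ensembles over repeated cross-validation partitions.

The predictor is an "ensemble of ensembles": the training set is partitioned
by R repetitions of k-fold cross-validation (default 100 x 10), one stochastic
gradient-boosted tree regressor is fit per training partition (R*k models),
and the final purity prediction for a sample is the bagging average of the
per-model predictions.  Models regress the logit of purity; predictions are
mapped back through the inverse logit before averaging so the final value
always lies in (0, 1).

Each model is an XGBoost least-squares booster grown with row and column
subsampling, stopped early when the validation fold's RMSE has not improved
for a fixed number of additional trees.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit

from .preprocess import (
    LOG2,
    LOGIT,
    ORIGINAL,
    DataError,
    ExpressionMatrix,
    PurityVector,
    logit_transform,
)

logger = logging.getLogger("purityboost")

#: Ten-gene marker panel for tumor purity prediction (stromal/immune genes).
TEN_GENE_PANEL = (
    "CSF2RB", "RHOH", "C1S", "CCDC69", "CCL22",
    "CYTIP", "POU2AF1", "FGR", "CCL21", "IL7R",
)


@dataclass(frozen=True)
class GBMConfig:
    """Hyperparameters of one boosted-tree regressor (least-squares loss).

    Defaults are the tuned pan-cancer parameter set: learning rate 0.05,
    depth 4, minimum leaf weight 1, 65% of genes and 85% of samples per
    tree, at most 5000 trees with early stopping after 5 non-improving
    trees.
    """

    learning_rate: float = 0.05
    max_depth: int = 4
    min_leaf_weight: float = 1.0
    colsample_per_tree: float = 0.65
    subsample_per_tree: float = 0.85
    max_trees: int = 5000
    early_stop_patience: int = 5
    #: Histogram resolution for split finding.  Log2 expression values are
    #: smooth, so 32 bins per feature loses nothing measurable while cutting
    #: single-thread training time severalfold.
    max_bin: int = 32

    def __post_init__(self) -> None:
        if self.max_bin < 2:
            raise ValueError("max_bin must be >= 2")
        if not (0 < self.colsample_per_tree <= 1 and 0 < self.subsample_per_tree <= 1):
            raise ValueError("sampling fractions must be in (0, 1]")
        if self.max_trees < 1 or self.early_stop_patience < 1:
            raise ValueError("max_trees and early_stop_patience must be >= 1")
        if self.learning_rate <= 0 or self.max_depth < 1 or self.min_leaf_weight < 0:
            raise ValueError("invalid learner parameters")

    def xgb_params(self, seed: int = 0) -> dict:
        return {
            "objective": "reg:squarederror",
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_leaf_weight,
            "colsample_bytree": self.colsample_per_tree,
            "subsample": self.subsample_per_tree,
            "tree_method": "hist",
            "max_bin": self.max_bin,
            "nthread": 1,
            "seed": int(seed) % (2**31),
            "verbosity": 0,
        }


#: Tuned pan-cancer defaults as a module-level constant.
DEFAULT_CONFIG = GBMConfig()


def default_grid() -> list[GBMConfig]:
    """A small published grid around the default parameter set (24 points)."""
    grid = []
    for lr in (0.05, 0.1, 0.3):
        for depth in (3, 4, 6):
            for colsample in (0.65, 1.0):
                grid.append(
                    GBMConfig(
                        learning_rate=lr,
                        max_depth=depth,
                        colsample_per_tree=colsample,
                        subsample_per_tree=0.85,
                        max_trees=500,
                    )
                )
    # a no-subsampling corner and the full default
    grid.append(GBMConfig(subsample_per_tree=1.0, colsample_per_tree=1.0, max_trees=500))
    grid.append(GBMConfig(max_trees=500))
    return grid


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Repetition x fold assignment of training samples.

    Each repetition is an independent random shuffle of the samples cut into
    ``n_folds`` contiguous blocks whose sizes differ by at most one; every
    sample appears in exactly one validation fold per repetition.
    """

    sample_ids: list[str]
    n_repetitions: int
    n_folds: int
    master_seed: int
    shuffle_seeds: list[int]
    fold_assignment: np.ndarray  # (n_repetitions, n_samples) -> fold index

    @property
    def n_models(self) -> int:
        return self.n_repetitions * self.n_folds


def _rep_seed(master_seed: int, rep: int) -> int:
    rng = np.random.default_rng([int(master_seed), int(rep)])
    return int(rng.integers(0, 2**31 - 1))


def _model_seed(master_seed: int, rep: int, fold: int) -> int:
    rng = np.random.default_rng([int(master_seed), int(rep), int(fold)])
    return int(rng.integers(0, 2**31 - 1))


def build_cv_plan(
    sample_ids: Sequence[str],
    n_repetitions: int = 100,
    n_folds: int = 10,
    master_seed: int = 0,
) -> CVPlan:
    """Build a repeated k-fold plan, deterministic given ``master_seed``."""
    n = len(sample_ids)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n_samples={n}")
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    seeds = [_rep_seed(master_seed, r) for r in range(n_repetitions)]
    assignment = np.empty((n_repetitions, n), dtype=np.int32)
    for r, s in enumerate(seeds):
        perm = np.random.default_rng(s).permutation(n)
        blocks = np.array_split(perm, n_folds)
        for f, block in enumerate(blocks):
            assignment[r, block] = f
    return CVPlan(
        sample_ids=list(sample_ids),
        n_repetitions=n_repetitions,
        n_folds=n_folds,
        master_seed=master_seed,
        shuffle_seeds=seeds,
        fold_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class ModelRecord:
    """Bookkeeping for one fitted member of the ensemble."""

    repetition: int
    fold: int
    seed: int
    n_trees: int
    val_rmse: float  # original purity scale
    val_pearson: float
    train_ids: list[str]


@dataclass
class FittedEnsemble:
    """An ordered collection of fitted boosters plus the plan that made them."""

    models: list[xgb.Booster]
    records: list[ModelRecord]
    plan: CVPlan
    config: GBMConfig
    gene_symbols: list[str]
    per_model_importance: np.ndarray  # genes x M, normalized per model
    skipped: list[tuple[int, int]] = field(default_factory=list)
    target_scale: str = LOGIT

    @property
    def n_models(self) -> int:
        return len(self.models)


def _fit_one(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: GBMConfig,
    seed: int,
    feature_names: list[str],
    monitor: str,
) -> tuple[xgb.Booster, np.ndarray]:
    dtrain = xgb.DMatrix(X[train_idx], label=y[train_idx], feature_names=feature_names)
    dval = xgb.DMatrix(X[val_idx], label=y[val_idx], feature_names=feature_names)
    evals = [(dtrain, "train")] if monitor == "train" else [(dval, "val")]
    booster = xgb.train(
        config.xgb_params(seed),
        dtrain,
        num_boost_round=config.max_trees,
        evals=evals,
        early_stopping_rounds=config.early_stop_patience,
        verbose_eval=False,
    )
    best = getattr(booster, "best_iteration", None)
    if best is not None and best + 1 < booster.num_boosted_rounds():
        booster = booster[: best + 1]
    val_pred = booster.predict(dval)
    return booster, val_pred


def _normalized_gain(booster: xgb.Booster, gene_symbols: list[str]) -> np.ndarray:
    """Per-gene split-gain totals of one model, normalized to sum to 1.

    The raw score for a gene is the total improvement in the squared-error
    objective over every split on that gene in every tree ("total gain",
    which weights each split by the observations it covers); dividing by the
    all-genes total yields the within-model importance share.
    """
    raw = booster.get_score(importance_type="total_gain")
    vec = np.zeros(len(gene_symbols))
    pos = {g: i for i, g in enumerate(gene_symbols)}
    for name, score in raw.items():
        vec[pos[name]] = score
    total = vec.sum()
    if total > 0:
        vec /= total
    return vec


def train_ensemble(
    m: ExpressionMatrix,
    p: PurityVector,
    config: GBMConfig = DEFAULT_CONFIG,
    plan: CVPlan | None = None,
    monitor: str = "validation",
) -> FittedEnsemble:
    """Fit one booster per (repetition, fold) partition of the plan.

    Each model trains on the ~90% partition and is early-stopped on the held
    validation fold (``monitor="train"`` monitors training error instead).
    Validation RMSE and Pearson correlation are recorded per model on the
    original purity scale.  Folds with a constant target are skipped with a
    warning, shrinking the ensemble rather than aborting.
    """
    if m.scale != LOG2:
        raise DataError("expression must be log2-scaled for training")
    if p.scale != LOGIT:
        raise DataError("purity target must be logit-scaled for training")
    if monitor not in ("validation", "train"):
        raise ValueError(f"unknown early-stopping monitor {monitor!r}")
    p = p.aligned_to(m)
    y = p.values
    if not np.all(np.isfinite(y)):
        raise DataError("non-finite target values")
    if plan is None:
        plan = build_cv_plan(m.sample_ids)
    if plan.sample_ids != m.sample_ids:
        raise DataError("plan sample IDs do not match the expression matrix")

    X = np.ascontiguousarray(m.data.to_numpy(dtype=np.float32))
    genes = m.gene_symbols
    ids = np.array(m.sample_ids)

    models: list[xgb.Booster] = []
    records: list[ModelRecord] = []
    importances: list[np.ndarray] = []
    skipped: list[tuple[int, int]] = []

    for r in range(plan.n_repetitions):
        folds = plan.fold_assignment[r]
        for f in range(plan.n_folds):
            val_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            if np.ptp(y[train_idx]) == 0 or len(val_idx) == 0:
                warnings.warn(
                    f"skipping degenerate partition (rep={r}, fold={f}): "
                    "constant target or empty validation fold"
                )
                skipped.append((r, f))
                continue
            seed = _model_seed(plan.master_seed, r, f)
            booster, val_pred = _fit_one(
                X, y, train_idx, val_idx, config, seed, genes, monitor
            )
            obs = expit(y[val_idx])
            pred = expit(val_pred)
            val_rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
            if np.ptp(pred) > 0 and np.ptp(obs) > 0:
                val_r = float(np.corrcoef(obs, pred)[0, 1])
            else:
                val_r = float("nan")
            models.append(booster)
            importances.append(_normalized_gain(booster, genes))
            records.append(
                ModelRecord(
                    repetition=r,
                    fold=f,
                    seed=seed,
                    n_trees=booster.num_boosted_rounds(),
                    val_rmse=val_rmse,
                    val_pearson=val_r,
                    train_ids=list(ids[train_idx]),
                )
            )
    if not models:
        raise DataError("no model could be trained (all partitions degenerate)")
    per_model_importance = np.column_stack(importances)
    return FittedEnsemble(
        models=models,
        records=records,
        plan=plan,
        config=config,
        gene_symbols=genes,
        per_model_importance=per_model_importance,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class PredictionResult:
    """Per-model and bagged-average purity predictions (original scale)."""

    sample_ids: list[str]
    per_model: np.ndarray  # M x n, original scale
    final: np.ndarray  # per-sample mean over models

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "predicted_purity": self.final}
        )


def predict(
    e: FittedEnsemble, m: ExpressionMatrix, avg_scale: str = "original"
) -> PredictionResult:
    """Bagged prediction: average per-model inverse-logit outputs.

    With ``avg_scale="original"`` (default) each model's logit-scale output
    is mapped to (0, 1) first and the mean is taken on the purity scale;
    ``avg_scale="logit"`` averages the raw logit outputs and maps the mean.
    Either way the final value lies strictly inside (0, 1).
    """
    if m.scale != LOG2:
        raise DataError("expression must be log2-scaled for prediction")
    if avg_scale not in ("original", "logit"):
        raise ValueError(f"unknown averaging scale {avg_scale!r}")
    missing = [g for g in e.gene_symbols if g not in m.data.columns]
    if missing:
        raise DataError(f"matrix lacks {len(missing)} training genes: {missing[:10]}")
    X = np.ascontiguousarray(
        m.data[e.gene_symbols].to_numpy(dtype=np.float32)
    )
    dm = xgb.DMatrix(X, feature_names=e.gene_symbols)
    logit_preds = np.vstack([mod.predict(dm) for mod in e.models])
    per_model = expit(logit_preds)
    if avg_scale == "original":
        final = per_model.mean(axis=0)
    else:
        final = expit(logit_preds.mean(axis=0))
    return PredictionResult(sample_ids=m.sample_ids, per_model=per_model, final=final)


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

def grid_search(
    m: ExpressionMatrix,
    p: PurityVector,
    grid: Sequence[GBMConfig],
    n_folds: int = 10,
    seed: int = 0,
    monitor: str = "validation",
) -> tuple[GBMConfig, pd.DataFrame]:
    """Select the config minimizing mean k-fold CV RMSE (original scale).

    Ties are broken toward the smaller ``learning_rate * max_trees`` product,
    then the smaller ``max_depth``, then grid order.  Returns the winning
    config and a per-config summary table.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    if p.scale != LOGIT:
        p = logit_transform(p)
    p = p.aligned_to(m)
    plan = build_cv_plan(m.sample_ids, n_repetitions=1, n_folds=n_folds, master_seed=seed)
    X = np.ascontiguousarray(m.data.to_numpy(dtype=np.float32))
    y = p.values
    genes = m.gene_symbols
    folds = plan.fold_assignment[0]

    rows = []
    for ci, config in enumerate(grid):
        fold_rmses = []
        for f in range(n_folds):
            val_idx = np.flatnonzero(folds == f)
            train_idx = np.flatnonzero(folds != f)
            try:
                booster, val_pred = _fit_one(
                    X, y, train_idx, val_idx, config,
                    _model_seed(seed, ci, f), genes, monitor,
                )
            except Exception as exc:
                raise RuntimeError(f"config #{ci} ({config}) failed to fit: {exc}") from exc
            fold_rmses.append(
                float(np.sqrt(np.mean((expit(y[val_idx]) - expit(val_pred)) ** 2)))
            )
        rows.append(
            {
                "config_index": ci,
                "cv_rmse_mean": float(np.mean(fold_rmses)),
                "cv_rmse_sd": float(np.std(fold_rmses, ddof=1)) if n_folds > 1 else 0.0,
                **asdict(config),
            }
        )
    summary = pd.DataFrame(rows)
    order = sorted(
        range(len(grid)),
        key=lambda i: (
            rows[i]["cv_rmse_mean"],
            grid[i].learning_rate * grid[i].max_trees,
            grid[i].max_depth,
            i,
        ),
    )
    best = grid[order[0]]
    logger.info("grid_search selected config #%d with CV RMSE %.4f",
                order[0], rows[order[0]]["cv_rmse_mean"])
    return best, summary


def restrict_and_retrain(
    m: ExpressionMatrix,
    p: PurityVector,
    panel: Sequence[str],
    grid: Sequence[GBMConfig] | None = None,
    n_repetitions: int = 100,
    n_folds: int = 10,
    master_seed: int = 0,
    tune_folds: int = 10,
) -> FittedEnsemble:
    """Re-run the whole pipeline on a restricted gene panel.

    Subsets the matrix to ``panel``, re-tunes hyperparameters on the panel
    with :func:`grid_search` (a restricted feature set generally wants its
    own settings), then trains a fresh repeated-CV ensemble.
    """
    missing = [g for g in panel if g not in m.data.columns]
    if missing:
        raise DataError(f"panel genes absent from matrix: {missing}")
    sub = m.subset_genes(panel)
    if p.scale != LOGIT:
        p = logit_transform(p)
    p = p.aligned_to(sub)
    if grid is None:
        grid = default_grid()
    best, _ = grid_search(sub, p, grid, n_folds=tune_folds, seed=master_seed)
    plan = build_cv_plan(sub.sample_ids, n_repetitions, n_folds, master_seed)
    return train_ensemble(sub, p, best, plan)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_ensemble(e: FittedEnsemble, out_dir: str | Path) -> Path:
    """Write a manifest plus one serialized booster file per model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(e.config),
        "plan": {
            "sample_ids": e.plan.sample_ids,
            "n_repetitions": e.plan.n_repetitions,
            "n_folds": e.plan.n_folds,
            "master_seed": e.plan.master_seed,
            "shuffle_seeds": e.plan.shuffle_seeds,
        },
        "gene_symbols": e.gene_symbols,
        "target_scale": e.target_scale,
        "skipped": e.skipped,
        "records": [
            {k: v for k, v in asdict(rec).items() if k != "train_ids"}
            for rec in e.records
        ],
        "train_ids": [rec.train_ids for rec in e.records],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.savetxt(out_dir / "importance.tsv", e.per_model_importance, delimiter="\t")
    for i, mod in enumerate(e.models):
        mod.save_model(str(out_dir / f"model_{i:04d}.json"))
    return out_dir


def load_ensemble(in_dir: str | Path) -> FittedEnsemble:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    config = GBMConfig(**manifest["config"])
    plan_info = manifest["plan"]
    plan = build_cv_plan(
        plan_info["sample_ids"],
        plan_info["n_repetitions"],
        plan_info["n_folds"],
        plan_info["master_seed"],
    )
    models = []
    records = []
    for i, rec in enumerate(manifest["records"]):
        booster = xgb.Booster()
        booster.load_model(str(in_dir / f"model_{i:04d}.json"))
        models.append(booster)
        records.append(ModelRecord(train_ids=manifest["train_ids"][i], **rec))
    importance = np.loadtxt(in_dir / "importance.tsv", delimiter="\t", ndmin=2)
    return FittedEnsemble(
        models=models,
        records=records,
        plan=plan,
        config=config,
        gene_symbols=manifest["gene_symbols"],
        per_model_importance=importance,
        skipped=[tuple(s) for s in manifest["skipped"]],
        target_scale=manifest["target_scale"],
    )
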