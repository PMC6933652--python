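"""Performance metrics, per-model summaries, and the permutation test.

All metrics are computed on the original [0, 1] purity scale: RMSE is
sqrt(mean squared error), correlations are Pearson's product-moment r and
Spearman's rank rho.  Per-model metric vectors are summarized by mean,
standard error (sample SD / sqrt(M)) and median.

The permutation test asks whether the bagged predictor's test-set accuracy
could arise by chance: the training purities are shuffled B times, the full
train+predict procedure is re-run on each shuffled dataset (test labels
untouched), and the add-one empirical p-value
(1 + #{null >= observed}) / (B + 1) is reported — always positive.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import logging
from pathlib import Path

import numpy as np
from scipy import stats

from .preprocess import (
    ORIGINAL,
    DataError,
    ExpressionMatrix,
    PurityVector,
    logit_transform,
)
from .ensemble import CVPlan, FittedEnsemble, GBMConfig, build_cv_plan, predict, train_ensemble

logger = logging.getLogger("purityboost")


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt((1/N) * sum (y_i - yhat_i)^2)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def correlations(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    """(Pearson r, Spearman rho); errors on constant input rather than NaN."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("correlation undefined for a constant vector")
    pearson = float(stats.pearsonr(y, yhat).statistic)
    spearman = float(stats.spearmanr(y, yhat).statistic)
    return pearson, spearman


def summarize_models(values: np.ndarray) -> dict[str, float]:
    """Mean, standard error (sample SD / sqrt(M); 0 when M=1) and median."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty metric vector")
    se = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return {"mean": float(np.mean(v)), "se": se, "median": float(np.median(v))}


@dataclass
class EvalSummary:
    """Per-model metric vectors, their summaries, and the bagged metrics."""

    per_model_rmse: np.ndarray
    per_model_pearson: np.ndarray
    per_model_spearman: np.ndarray
    rmse_summary: dict[str, float]
    pearson_summary: dict[str, float]
    spearman_summary: dict[str, float]
    final_rmse: float
    final_pearson: float
    final_spearman: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_model": {
                "rmse": self.per_model_rmse.tolist(),
                "pearson": self.per_model_pearson.tolist(),
                "spearman": self.per_model_spearman.tolist(),
            },
            "summaries": {
                "rmse": self.rmse_summary,
                "pearson": self.pearson_summary,
                "spearman": self.spearman_summary,
            },
            "final": {
                "rmse": self.final_rmse,
                "pearson": self.final_pearson,
                "spearman": self.final_spearman,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def evaluate_predictions(per_model: np.ndarray, final: np.ndarray,
                         truth: PurityVector) -> EvalSummary:
    """Score per-model and bagged predictions against observed purity."""
    if truth.scale != ORIGINAL:
        raise DataError("truth must be on the original purity scale")
    y = truth.values
    M = per_model.shape[0]
    pm_rmse = np.empty(M)
    pm_pear = np.empty(M)
    pm_spear = np.empty(M)
    for i in range(M):
        pm_rmse[i] = rmse(y, per_model[i])
        pm_pear[i], pm_spear[i] = correlations(y, per_model[i])
    fp, fs = correlations(y, final)
    return EvalSummary(
        per_model_rmse=pm_rmse,
        per_model_pearson=pm_pear,
        per_model_spearman=pm_spear,
        rmse_summary=summarize_models(pm_rmse),
        pearson_summary=summarize_models(pm_pear),
        spearman_summary=summarize_models(pm_spear),
        final_rmse=rmse(y, final),
        final_pearson=fp,
        final_spearman=fs,
    )


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and the empirical p-value."""

    observed_statistic: float
    null_statistics: np.ndarray
    empirical_p: float
    B: int
    statistic_name: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "observed_statistic": self.observed_statistic,
                    "null_statistics": self.null_statistics.tolist(),
                    "empirical_p": self.empirical_p,
                    "B": self.B,
                    "statistic_name": self.statistic_name,
                },
                indent=1,
            )
        )


def _run_once(
    m_train: ExpressionMatrix,
    y_train_logit: PurityVector,
    m_test: ExpressionMatrix,
    y_test: np.ndarray,
    config: GBMConfig,
    plan: CVPlan,
    statistic: str,
) -> float:
    ens = train_ensemble(m_train, y_train_logit, config, plan)
    pred = predict(ens, m_test)
    if statistic == "pearson":
        return correlations(y_test, pred.final)[0]
    return -rmse(y_test, pred.final)


def permutation_test(
    m_train: ExpressionMatrix,
    p_train: PurityVector,
    m_test: ExpressionMatrix,
    p_test: PurityVector,
    config: GBMConfig,
    n_repetitions: int = 1,
    n_folds: int = 3,
    B: int = 19,
    master_seed: int = 0,
    statistic: str = "pearson",
) -> PermutationResult:
    """Label-permutation significance test for the bagged predictor.

    The observed statistic is the test-set Pearson r (or negative RMSE) of
    an ensemble trained on the true training labels with a reduced
    repetition/fold plan.  For each of B permutations the training purities
    are shuffled uniformly at random, the identical procedure is re-run, and
    the statistic recorded; test labels are never touched.  The reported
    p-value uses the add-one formula, so it is never zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if statistic not in ("pearson", "neg_rmse"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if p_train.scale != ORIGINAL or p_test.scale != ORIGINAL:
        raise DataError("purity inputs must be on the original scale")
    p_train = p_train.aligned_to(m_train)
    p_test = p_test.aligned_to(m_test)
    plan = build_cv_plan(m_train.sample_ids, n_repetitions, n_folds, master_seed)

    observed = _run_once(
        m_train, logit_transform(p_train), m_test, p_test.values,
        config, plan, statistic,
    )
    rng = np.random.default_rng([int(master_seed), 0x5EED])
    null = np.empty(B)
    for b in range(B):
        shuffled = PurityVector(
            p_train.sample_ids, rng.permutation(p_train.values), ORIGINAL
        )
        null[b] = _run_once(
            m_train, logit_transform(shuffled), m_test, p_test.values,
            config, plan, statistic,
        )
        logger.debug("permutation %d/%d: %s = %.4f", b + 1, B, statistic, null[b])
    p_val = (1 + int(np.sum(null >= observed))) / (B + 1)
    return PermutationResult(
        observed_statistic=float(observed),
        null_statistics=null,
        empirical_p=float(p_val),
        B=B,
        statistic_name=statistic,
    )
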