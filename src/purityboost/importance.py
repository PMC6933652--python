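"""Gene importance aggregation and marker-panel extraction.

Within one boosted model the importance of gene g is its split-gain total
over all trees divided by the split-gain total over all genes and trees, so
each model's scores are nonnegative and sum to one.  Across the ensemble a
gene is *eligible* for ranking only if its score is non-zero in every model;
eligible genes are ordered by their median within-model rank (descending
score, average ties), with median- and mean-score orderings available as
alternatives.  The top of the ordering is the candidate marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RANK_STATS = ("median-rank", "median-score", "mean-score")


@dataclass
class ImportanceTable:
    """Per-model normalized importance scores with cross-model aggregates."""

    gene_symbols: list[str]
    per_model_scores: np.ndarray  # genes x M
    eligible: np.ndarray  # bool per gene
    ranks: np.ndarray  # genes x M, within-model ranks (1 = best)
    median_rank: np.ndarray
    mean_score: np.ndarray
    median_score: np.ndarray
    final_order: list[str]  # eligible genes, best first
    rank_stat: str

    @property
    def n_models(self) -> int:
        return self.per_model_scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        final_rank = {g: i + 1 for i, g in enumerate(self.final_order)}
        return pd.DataFrame(
            {
                "gene": self.gene_symbols,
                "mean_score": self.mean_score,
                "median_score": self.median_score,
                "median_rank": self.median_rank,
                "eligible": self.eligible,
                "final_rank": [final_rank.get(g, np.nan) for g in self.gene_symbols],
            }
        )


def model_importance(tree_scores: np.ndarray) -> np.ndarray:
    """Normalize per-tree per-gene split-gain sums into one model's scores.

    Parameters
    ----------
    tree_scores
        Array of shape (n_trees, n_genes) — or (n_genes,) if already summed
        over trees — of nonnegative split-gain totals S_gt.

    Returns the per-gene share ``sum_t S_gt / sum_t sum_g S_gt``, which sums
    to exactly 1.
    """
    arr = np.asarray(tree_scores, dtype=float)
    if arr.ndim == 1:
        per_gene = arr.copy()
    elif arr.ndim == 2:
        per_gene = arr.sum(axis=0)
    else:
        raise ValueError("tree_scores must be 1- or 2-dimensional")
    if np.any(per_gene < 0):
        raise ValueError("split-gain scores must be nonnegative")
    total = per_gene.sum()
    if total == 0:
        raise ValueError("all-zero importance: the model made no splits")
    return per_gene / total


def aggregate_importance(
    per_model: np.ndarray,
    gene_symbols: Sequence[str],
    rank_stat: str = "median-rank",
) -> ImportanceTable:
    """Aggregate per-model scores into an ordered gene ranking.

    Ranks are computed per model over *all* genes by descending score, with
    tied scores (including the block of zero-score genes) sharing their
    average rank.  A gene is eligible iff its score is positive in every
    model.  The final ordering over eligible genes uses ``rank_stat``:

    - ``"median-rank"`` (default): ascending median within-model rank;
    - ``"median-score"``: descending median score;
    - ``"mean-score"``: descending mean score.

    Remaining ties are broken by descending mean score, then gene symbol.
    """
    if rank_stat not in RANK_STATS:
        raise ValueError(f"rank_stat must be one of {RANK_STATS}")
    scores = np.asarray(per_model, dtype=float)
    if scores.ndim != 2:
        raise ValueError("per_model must be a genes x models matrix")
    genes = list(gene_symbols)
    if len(genes) != scores.shape[0]:
        raise ValueError("gene_symbols length does not match score matrix")
    if scores.shape[1] < 1:
        raise ValueError("need at least one model")

    ranks = np.column_stack(
        [rankdata(-scores[:, m], method="average") for m in range(scores.shape[1])]
    )
    eligible = np.all(scores > 0, axis=1)
    median_rank = np.median(ranks, axis=1)
    mean_score = scores.mean(axis=1)
    median_score = np.median(scores, axis=1)

    idx = np.flatnonzero(eligible)
    if rank_stat == "median-rank":
        keys = [(median_rank[i], -mean_score[i], genes[i]) for i in idx]
    elif rank_stat == "median-score":
        keys = [(-median_score[i], -mean_score[i], genes[i]) for i in idx]
    else:
        keys = [(-mean_score[i], genes[i]) for i in idx]
    order = [genes[i] for _, i in sorted(zip(keys, idx), key=lambda t: t[0])]

    return ImportanceTable(
        gene_symbols=genes,
        per_model_scores=scores,
        eligible=eligible,
        ranks=ranks,
        median_rank=median_rank,
        mean_score=mean_score,
        median_score=median_score,
        final_order=order,
        rank_stat=rank_stat,
    )


def top_k_panel(table: ImportanceTable, k: int) -> list[str]:
    """The first ``k`` genes of the final ordering."""
    n_eligible = len(table.final_order)
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k > n_eligible:
        raise ValueError(f"k={k} exceeds the {n_eligible} eligible genes")
    return table.final_order[:k]


def write_importance(table: ImportanceTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_panel(panel: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(panel) + "\n")


def read_panel(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
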