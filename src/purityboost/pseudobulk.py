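"""Pseudo-bulk construction from single-cell counts and harmonization.

A pseudo-bulk profile is the per-gene sum of raw counts over all cells of a
sample.  To predict purity for pseudo-bulk samples with a model trained on a
reference bulk cohort, the two datasets are merged on their common genes,
every sample is rescaled so its median expression matches the median of the
reference samples' medians, and values are mapped to log2(count + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

from .preprocess import (
    LOG2,
    RAW,
    DataError,
    ExpressionMatrix,
)
from .synthetic import SyntheticSingleCell


@dataclass
class CellCountMatrix:
    """Cells x genes nonnegative counts with a cell-to-sample mapping."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_symbols: list[str]
    sample_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_symbols)):
            raise DataError("counts shape does not match cell/gene lists")
        if np.any(self.counts < 0):
            raise DataError("counts must be nonnegative")
        unmapped = [c for c in self.cell_ids if c not in self.sample_of]
        if unmapped:
            raise DataError(f"cells without sample assignment: {unmapped[:5]}")

    @classmethod
    def from_synthetic(cls, sc: SyntheticSingleCell) -> "CellCountMatrix":
        return cls(
            counts=sc.counts,
            cell_ids=sc.cell_ids,
            gene_symbols=sc.gene_symbols,
            sample_of=sc.sample_of,
        )


def read_cells_mtx(
    in_dir: str | Path, orientation: str = "genes_by_cells"
) -> CellCountMatrix:
    """Read MatrixMarket counts plus genes.tsv / barcodes.tsv / labels.tsv.

    ``labels.tsv`` rows are ``cell_id<TAB>sample_id[<TAB>label]``.
    """
    in_dir = Path(in_dir)
    mat = np.asarray(mmread(str(in_dir / "matrix.mtx")).todense())
    if orientation == "genes_by_cells":
        mat = mat.T
    elif orientation != "cells_by_genes":
        raise DataError(f"unknown orientation {orientation!r}")
    genes = [l.strip() for l in (in_dir / "genes.tsv").read_text().splitlines() if l.strip()]
    cells = [l.strip() for l in (in_dir / "barcodes.tsv").read_text().splitlines() if l.strip()]
    labels = pd.read_csv(in_dir / "labels.tsv", sep="\t", header=None)
    sample_of = dict(zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1].astype(str)))
    return CellCountMatrix(mat, cells, genes, sample_of)


def aggregate_to_bulk(c: CellCountMatrix) -> ExpressionMatrix:
    """Sum raw counts per gene over each sample's cells (raw-scale bulk)."""
    samples = [c.sample_of[cid] for cid in c.cell_ids]
    df = pd.DataFrame(np.asarray(c.counts, dtype=float),
                      index=c.cell_ids, columns=c.gene_symbols)
    bulk = df.groupby(pd.Series(samples, index=df.index), sort=True).sum()
    bulk.index.name = None
    return ExpressionMatrix(bulk, RAW)


def merge_common_genes(
    bulk_a: ExpressionMatrix, bulk_b: ExpressionMatrix
) -> ExpressionMatrix:
    """Stack two raw-scale bulk matrices on their shared genes.

    Genes are intersected by exact symbol (order follows ``bulk_a``); rows
    are the union of samples, which must be disjoint between the inputs.
    """
    if bulk_a.scale != RAW or bulk_b.scale != RAW:
        raise DataError("both matrices must be raw-scale for merging")
    overlap = set(bulk_a.sample_ids) & set(bulk_b.sample_ids)
    if overlap:
        raise DataError(f"sample IDs shared between inputs: {sorted(overlap)[:5]}")
    b_genes = set(bulk_b.gene_symbols)
    common = [g for g in bulk_a.gene_symbols if g in b_genes]
    if not common:
        raise DataError("no genes in common between the two matrices")
    dropped_a = bulk_a.n_genes - len(common)
    dropped_b = bulk_b.n_genes - len(common)
    if dropped_a or dropped_b:
        import logging

        logging.getLogger("purityboost").info(
            "merge_common_genes kept %d genes (dropped %d from A, %d from B)",
            len(common), dropped_a, dropped_b,
        )
    merged = pd.concat([bulk_a.data[common], bulk_b.data[common]], axis=0)
    return ExpressionMatrix(merged, RAW)


def median_center_normalize(
    merged: ExpressionMatrix,
    reference_ids: Sequence[str],
    mode: str = "multiplicative",
) -> ExpressionMatrix:
    """Center every sample on the reference samples' median-of-medians.

    Let m_i be sample i's median expression over genes and c the median of
    m_i over the reference samples (midpoint convention for even counts).

    - ``"multiplicative"`` (default): each value is scaled by c / m_i on the
      count scale, moving every sample's median to c, then mapped through
      log2(value + 1).  Counts stay nonnegative.
    - ``"additive-log"``: values are mapped through log2(value + 1) first
      and each sample is shifted by log2(c + 1) minus its own log-scale
      median.

    Both maps are strictly increasing within a sample, so within-sample
    rank order is preserved.
    """
    if merged.scale != RAW:
        raise DataError("normalization expects raw-scale input")
    missing = [s for s in reference_ids if s not in merged.data.index]
    if missing:
        raise DataError(f"reference samples absent from matrix: {missing[:5]}")
    if mode not in ("multiplicative", "additive-log"):
        raise DataError(f"unknown normalization mode {mode!r}")

    vals = merged.data
    medians = vals.median(axis=1)
    zero_med = medians.index[medians == 0].tolist()
    if zero_med and mode == "multiplicative":
        raise DataError(f"sample(s) with zero median expression: {zero_med[:5]}")
    c = float(np.median(medians.loc[list(reference_ids)].to_numpy()))

    if mode == "multiplicative":
        scaled = vals.mul(c / medians, axis=0)
        out = np.log2(scaled + 1.0)
    else:
        logv = np.log2(vals + 1.0)
        log_medians = logv.median(axis=1)
        out = logv.add(np.log2(c + 1.0) - log_medians, axis=0)
        out = out.clip(lower=0.0)
    return ExpressionMatrix(out, LOG2)
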