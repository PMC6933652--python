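"""Loading, validation and transformation of expression and purity data.

Bulk expression matrices are held as samples x genes pandas DataFrames with a
declared scale (``raw`` normalized counts or ``log2``).  Purity values live in
[0, 1] ("original" scale) or on the real line after a logit transform; the
regression target is always the logit image so that predictions mapped back
through the inverse logit stay inside (0, 1).

The transformation pipeline mirrors a standard bulk RNA-seq preparation:
floor normalized counts at 1 and take log2, drop genes with missing values or
zero variance, keep one sample per patient, then logit-transform the purity
labels after reassigning boundary values to fixed interior constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit as _expit
from scipy.special import logit as _logit

logger = logging.getLogger("purityboost")

#: Purity of exactly 1 is reassigned to this constant before the logit
#: transform; 0 is reassigned symmetrically to ``1 - PURITY_UPPER``.
PURITY_UPPER = 0.9975
PURITY_LOWER = 1.0 - PURITY_UPPER

RAW = "raw"
LOG2 = "log2"
ORIGINAL = "original"
LOGIT = "logit"


class DataError(ValueError):
    """Raised for malformed or invariant-violating input data."""


@dataclass
class ExpressionMatrix:
    """Samples x genes expression table with a declared value scale.

    Parameters
    ----------
    data
        DataFrame indexed by sample ID with gene symbols as columns.
    scale
        ``"raw"`` (nonnegative normalized counts) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise DataError(f"unknown expression scale {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene symbols: {dups[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise DataError(f"unknown sample IDs: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(sample_ids)], self.scale)

    def subset_genes(self, gene_symbols: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in gene_symbols if g not in self.data.columns]
        if missing:
            raise DataError(f"unknown gene symbols: {missing[:5]}")
        return ExpressionMatrix(self.data[list(gene_symbols)], self.scale)


@dataclass
class PurityVector:
    """Per-sample purity values with a scale flag.

    ``original`` values lie in [0, 1] (clamped to
    [``PURITY_LOWER``, ``PURITY_UPPER``] by :func:`logit_transform`);
    ``logit`` values are finite reals.
    """

    sample_ids: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in (ORIGINAL, LOGIT):
            raise DataError(f"unknown purity scale {self.scale!r}")
        if len(self.sample_ids) != len(self.values):
            raise DataError("sample_ids and values lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DataError("duplicate sample IDs in purity vector")
        if not np.all(np.isfinite(self.values)):
            raise DataError("purity values must be finite")

    def subset(self, sample_ids: Sequence[str]) -> "PurityVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataError(f"unknown sample IDs in purity vector: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return PurityVector(list(sample_ids), self.values[idx], self.scale)

    def aligned_to(self, m: ExpressionMatrix) -> "PurityVector":
        """Reorder to the sample order of ``m`` (every sample must be present)."""
        return self.subset(m.sample_ids)


@dataclass
class SplitPlan:
    """A disjoint train/test partition of sample IDs."""

    train_ids: list[str]
    test_ids: list[str]
    seed: int
    train_fraction: float

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise DataError("train and test sets overlap")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # pandas silently renames duplicated header labels, so check them raw
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_header = [h for h in set(header) if header.count(h) > 1]
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise DataError(f"{path} has no data columns")
    if dup_header:
        df.columns = header  # restore the true (duplicated) labels
    return df


def load_expression(
    path: str | Path,
    orientation: str = "genes_by_samples",
    collapse_duplicates: str | None = None,
) -> ExpressionMatrix:
    """Load a delimited expression matrix as raw-scale samples x genes.

    Parameters
    ----------
    path
        TSV (default) or CSV file with one header row and an ID column.
    orientation
        ``"genes_by_samples"`` (rows are genes) or ``"samples_by_genes"``.
    collapse_duplicates
        Policy for duplicated gene symbols: ``None`` (error), ``"mean"`` or
        ``"first"``.

    Missing cells spelled ``NA`` (or empty) are kept as NaN; remove them with
    :func:`filter_genes`.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise DataError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "genes_by_samples":
        df = df.T
    # rows are now samples, columns genes
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample IDs: {dups[:5]}")
    for j in range(df.shape[1]):
        col = df.iloc[:, j]
        if pd.api.types.is_numeric_dtype(col):
            continue
        coerced = pd.to_numeric(col, errors="coerce")
        newly_nan = coerced.isna() & col.notna()
        if newly_nan.any():
            row = df.index[newly_nan.to_numpy().argmax()]
            raise DataError(
                f"non-numeric value in column {df.columns[j]!r}, row {row!r}: "
                f"{col.loc[row]!r}"
            )
        df.isetitem(j, coerced)
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        if collapse_duplicates is None:
            raise DataError(
                f"duplicate gene symbols {dups[:5]}; pass collapse_duplicates="
                "'mean' or 'first' to resolve"
            )
        if collapse_duplicates == "mean":
            df = df.T.groupby(level=0, sort=False).mean().T
        elif collapse_duplicates == "first":
            df = df.loc[:, ~df.columns.duplicated()]
        else:
            raise DataError(f"unknown collapse policy {collapse_duplicates!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), RAW)


def load_purity(path: str | Path) -> PurityVector:
    """Load a two-column ``sample_id<TAB>purity`` file (original scale)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 2:
        # allow a header row
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] != 2:
            raise DataError(f"{path}: expected exactly two columns")
    ids = df.iloc[:, 0].astype(str).tolist()
    vals = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(dtype=float)
    return PurityVector(ids, vals, ORIGINAL)


def write_purity(p: PurityVector, path: str | Path) -> None:
    pd.DataFrame({"sample_id": p.sample_ids, "purity": p.values}).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_expression(
    m: ExpressionMatrix, path: str | Path, orientation: str = "genes_by_samples"
) -> None:
    df = m.data.T if orientation == "genes_by_samples" else m.data
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log2_floor_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Floor raw values at 1 and take log2, yielding a nonnegative matrix.

    Values below 1 are assigned 1 before transformation, so the log2 output
    has a hard floor at 0.  Applying this to an already log2-scaled matrix is
    an error; the scale flag prevents double transformation.
    """
    if m.scale != RAW:
        raise DataError("matrix is already log2-scaled; refusing to re-transform")
    vals = m.data.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise DataError("raw expression values must be nonnegative")
    out = np.log2(np.maximum(vals, 1.0))
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns), LOG2)


def filter_genes(
    m: ExpressionMatrix, return_removed: bool = False
) -> ExpressionMatrix | tuple[ExpressionMatrix, list[str]]:
    """Drop genes with any missing value or zero variance across samples."""
    vals = m.data
    has_missing = vals.isna().any(axis=0)
    variances = vals.var(axis=0, ddof=0)
    zero_var = variances.fillna(0.0) == 0.0
    drop = has_missing | zero_var
    removed = list(vals.columns[drop])
    if len(removed) == vals.shape[1]:
        raise DataError("all genes removed by filtering")
    if removed:
        logger.info("filter_genes removed %d genes: %s%s", len(removed),
                    removed[:10], "..." if len(removed) > 10 else "")
    out = ExpressionMatrix(vals.loc[:, ~drop], m.scale)
    if return_removed:
        return out, removed
    return out


def dedupe_samples(
    m: ExpressionMatrix, patient_of: Mapping[str, str]
) -> ExpressionMatrix:
    """Keep at most one sample per patient.

    When a patient has several samples the one with the lexicographically
    smallest sample ID is retained (a deterministic, arbitrary rule).
    """
    missing = [s for s in m.sample_ids if s not in patient_of]
    if missing:
        raise DataError(f"samples without patient assignment: {missing[:5]}")
    keep_by_patient: dict[str, str] = {}
    for s in m.sample_ids:
        p = patient_of[s]
        if p not in keep_by_patient or s < keep_by_patient[p]:
            keep_by_patient[p] = s
    keep = set(keep_by_patient.values())
    kept = [s for s in m.sample_ids if s in keep]
    return ExpressionMatrix(m.data.loc[kept], m.scale)


def logit_transform(p: PurityVector) -> PurityVector:
    """Map original-scale purity to the real line via ln(v / (1 - v)).

    Boundary values are first reassigned to fixed interior constants: 1.00
    becomes ``PURITY_UPPER`` (0.9975) and, symmetrically, 0.00 becomes
    ``PURITY_LOWER``.  Values already beyond those constants are clamped to
    them, so the logit is always finite.
    """
    if p.scale != ORIGINAL:
        raise DataError("purity vector is already on the logit scale")
    v = p.values
    if np.any((v < 0) | (v > 1)):
        bad = v[(v < 0) | (v > 1)]
        raise DataError(f"purity values outside [0, 1]: {bad[:5]}")
    clamped = np.clip(v, PURITY_LOWER, PURITY_UPPER)
    return PurityVector(p.sample_ids, _logit(clamped), LOGIT)


def inverse_logit(p: PurityVector) -> PurityVector:
    """Map logit-scale values back to (0, 1) via 1 / (1 + e^-v)."""
    if p.scale != LOGIT:
        raise DataError("purity vector is not on the logit scale")
    return PurityVector(p.sample_ids, _expit(p.values), ORIGINAL)


def split_train_test(
    m: ExpressionMatrix,
    p: PurityVector,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
) -> SplitPlan:
    """Randomly partition samples into train/test; |train| = round(fraction*n)."""
    if not (0.0 < fraction < 1.0):
        raise DataError(f"train fraction must be in (0, 1), got {fraction}")
    if set(m.sample_ids) != set(p.sample_ids):
        raise DataError("expression and purity sample IDs do not match")
    ids = np.array(m.sample_ids)
    n = len(ids)
    if n < 2:
        raise DataError("need at least 2 samples to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitPlan(
        train_ids=list(ids[perm[:n_train]]),
        test_ids=list(ids[perm[n_train:]]),
        seed=seed,
        train_fraction=fraction,
    )
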