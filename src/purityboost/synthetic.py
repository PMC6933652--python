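"""Synthetic bulk and single-cell data with known tumor purity.

The bulk generator emulates the statistical structure that makes purity
predictable from expression: a tumor sample is a mixture of cancer cells and
stroma, and a minority of "stromal" marker genes (immune/fibroblast genes in
real tumors) have expression that decreases monotonically with purity on the
log2 scale.  Non-marker genes carry no purity signal.  Per-tumor-type batch
shifts and additive Gaussian noise provide realistic nuisance structure.

The single-cell sampler draws each cell's identity (cancer vs. stromal) from
a Bernoulli with the sample's purity and its gene counts from a Poisson with
the identity's rate profile; the realized cancer-cell fraction per sample is
the ground-truth purity, mirroring how cell-type annotations define purity in
real single-cell studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .preprocess import (
    LOG2,
    ORIGINAL,
    ExpressionMatrix,
    PurityVector,
    write_expression,
    write_purity,
)


@dataclass
class SyntheticTruth:
    """Generator parameters plus the ground truth they imply."""

    n_samples: int
    n_genes: int
    n_markers: int
    purity: np.ndarray
    marker_genes: list[str]
    effect_size: float
    noise_sd: float
    n_types: int
    type_shift_sd: float
    seed: int
    type_of_sample: np.ndarray | None = None


@dataclass
class SyntheticSingleCell:
    """Cells x genes counts with cell labels and per-sample truth."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_symbols: list[str]
    cell_labels: np.ndarray  # "cancer" | "stromal"
    sample_of: dict[str, str]
    true_purity_by_sample: dict[str, float]


def simulate_bulk(
    n_samples: int = 600,
    n_genes: int = 2000,
    n_markers: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 0.5,
    n_types: int = 3,
    type_shift_sd: float = 0.5,
    purity_alpha: float = 2.0,
    purity_beta: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PurityVector, SyntheticTruth]:
    """Generate a log2-scale bulk expression matrix with planted purity signal.

    Model
    -----
    purity ``p_i ~ Beta(purity_alpha, purity_beta)`` clipped to [0.01, 0.99];
    gene baselines ``mu_g ~ Uniform(2, 10)``; per-type batch shifts
    ``delta_{tg} ~ Normal(0, type_shift_sd)``; noise
    ``eps ~ Normal(0, noise_sd)``.  Non-marker genes:
    ``x_ig = mu_g + delta_{t(i)g} + eps``.  Marker (stromal) genes add
    ``effect_size * (1 - p_i)``, so their expression decreases monotonically
    with purity.  Values are floored at 0 to respect the log2-scale
    nonnegativity invariant (the floor is essentially never hit at the
    default baselines).  Deterministic given ``seed``.

    Returns the expression matrix (scale ``log2``), the true purity vector,
    and a :class:`SyntheticTruth` record naming the planted marker genes.
    """
    if not 0 <= n_markers < n_genes:
        raise ValueError("need 0 <= n_markers < n_genes")
    if min(noise_sd, type_shift_sd) < 0:
        raise ValueError("variance parameters must be nonnegative")
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    rng = np.random.default_rng(seed)

    purity = np.clip(rng.beta(purity_alpha, purity_beta, size=n_samples), 0.01, 0.99)
    width = len(str(n_genes))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    marker_idx = rng.choice(n_genes, size=n_markers, replace=False)
    marker_set = [genes[i] for i in sorted(marker_idx)]

    mu = rng.uniform(2.0, 10.0, size=n_genes)
    types = rng.integers(0, n_types, size=n_samples)
    delta = rng.normal(0.0, type_shift_sd, size=(n_types, n_genes)) if type_shift_sd > 0 else np.zeros((n_types, n_genes))
    eps = rng.normal(0.0, noise_sd, size=(n_samples, n_genes)) if noise_sd > 0 else np.zeros((n_samples, n_genes))

    x = mu[None, :] + delta[types, :] + eps
    if n_markers:
        x[:, marker_idx] += effect_size * (1.0 - purity)[:, None]
    np.maximum(x, 0.0, out=x)

    m = ExpressionMatrix(pd.DataFrame(x, index=samples, columns=genes), LOG2)
    p = PurityVector(samples, purity, ORIGINAL)
    truth = SyntheticTruth(
        n_samples=n_samples,
        n_genes=n_genes,
        n_markers=n_markers,
        purity=purity,
        marker_genes=marker_set,
        effect_size=effect_size,
        noise_sd=noise_sd,
        n_types=n_types,
        type_shift_sd=type_shift_sd,
        seed=seed,
        type_of_sample=types,
    )
    return m, p, truth


def simulate_cells(
    n_samples: int,
    cells_per_sample: int,
    purity_by_sample: np.ndarray,
    profiles: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
    gene_symbols: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> SyntheticSingleCell:
    """Sample single-cell counts for a set of mixed tumor samples.

    Each cell of sample *i* is labeled cancer with probability
    ``purity_by_sample[i]`` and stromal otherwise; its per-gene counts are
    independent Poisson draws with the rate profile of its label.  The
    realized cancer-cell fraction per sample is recorded as the ground-truth
    purity.

    Parameters
    ----------
    profiles
        ``(cancer_rates, stromal_rates)`` — nonnegative per-gene Poisson
        rates sharing one gene set.
    """
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    cancer_rates, stromal_rates = (np.asarray(p, dtype=float) for p in profiles)
    if cancer_rates.shape != stromal_rates.shape:
        raise ValueError("profiles must share one gene set")
    if np.any(cancer_rates < 0) or np.any(stromal_rates < 0):
        raise ValueError("Poisson rates must be nonnegative")
    purity_by_sample = np.asarray(purity_by_sample, dtype=float)
    if purity_by_sample.shape != (n_samples,):
        raise ValueError("purity_by_sample must have length n_samples")
    if np.any((purity_by_sample < 0) | (purity_by_sample > 1)):
        raise ValueError("purities must lie in [0, 1]")

    n_genes = len(cancer_rates)
    if gene_symbols is None:
        gene_symbols = [f"G{i:0{len(str(n_genes))}d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"SC{i:03d}" for i in range(n_samples)]

    rng = np.random.default_rng(seed)
    n_cells = n_samples * cells_per_sample
    sample_index = np.repeat(np.arange(n_samples), cells_per_sample)
    is_cancer = rng.random(n_cells) < purity_by_sample[sample_index]
    rates = np.where(is_cancer[:, None], cancer_rates[None, :], stromal_rates[None, :])
    counts = rng.poisson(rates)

    cell_ids = [f"{sample_ids[s]}_c{j:05d}" for j, s in enumerate(sample_index)]
    sample_of = {c: sample_ids[s] for c, s in zip(cell_ids, sample_index)}
    labels = np.where(is_cancer, "cancer", "stromal")
    true_purity = {
        sample_ids[s]: float(is_cancer[sample_index == s].mean())
        for s in range(n_samples)
    }
    return SyntheticSingleCell(
        counts=counts,
        cell_ids=cell_ids,
        gene_symbols=gene_symbols,
        cell_labels=labels,
        sample_of=sample_of,
        true_purity_by_sample=true_purity,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_bulk(
    m: ExpressionMatrix, p: PurityVector, out_dir: str | Path, prefix: str = "bulk"
) -> tuple[Path, Path]:
    """Write a bulk matrix (genes x samples TSV) and its purity TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mpath = out_dir / f"{prefix}_expression.tsv"
    ppath = out_dir / f"{prefix}_purity.tsv"
    write_expression(m, mpath, orientation="genes_by_samples")
    write_purity(p, ppath)
    return mpath, ppath


def write_cells(sc: SyntheticSingleCell, out_dir: str | Path) -> Path:
    """Write single-cell counts as MatrixMarket plus side files.

    Produces ``matrix.mtx`` (genes x cells, the common convention),
    ``genes.tsv``, ``barcodes.tsv`` and ``labels.tsv``
    (cell_id, sample_id, label).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(sc.counts.T)  # genes x cells
    mmwrite(str(out_dir / "matrix.mtx"), mat, field="integer")
    (out_dir / "genes.tsv").write_text("\n".join(sc.gene_symbols) + "\n")
    (out_dir / "barcodes.tsv").write_text("\n".join(sc.cell_ids) + "\n")
    with open(out_dir / "labels.tsv", "w") as fh:
        for c, lab in zip(sc.cell_ids, sc.cell_labels):
            fh.write(f"{c}\t{sc.sample_of[c]}\t{lab}\n")
    return out_dir
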