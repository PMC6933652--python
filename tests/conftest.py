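import numpy as np
import pandas as pd
import pytest

from purityboost import (
    ExpressionMatrix,
    PurityVector,
    simulate_bulk,
)
from purityboost.preprocess import LOG2, ORIGINAL, RAW


@pytest.fixture
def tiny_raw_matrix() -> ExpressionMatrix:
    """3 samples x 4 genes, raw scale, handmade values."""
    df = pd.DataFrame(
        [[0.5, 8.0, 1.0, 2.0],
         [4.0, 2.0, 1.0, 16.0],
         [1.0, 0.0, 1.0, 4.0]],
        index=["s1", "s2", "s3"],
        columns=["GA", "GB", "GC", "GD"],
    )
    return ExpressionMatrix(df, RAW)


@pytest.fixture
def tiny_purity() -> PurityVector:
    return PurityVector(["s1", "s2", "s3"], np.array([0.2, 0.5, 0.9]), ORIGINAL)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small but learnable dataset shared across training tests."""
    return simulate_bulk(
        n_samples=120, n_genes=200, n_markers=10,
        effect_size=2.0, noise_sd=0.5, n_types=2, seed=7,
    )


def make_log2_matrix(values, sample_ids=None, gene_symbols=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    gene_symbols = gene_symbols or [f"g{j}" for j in range(g)]
    return ExpressionMatrix(
        pd.DataFrame(values, index=sample_ids, columns=gene_symbols), LOG2
    )
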