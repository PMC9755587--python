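import numpy as np
import pandas as pd
import pytest

from coexq import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """Small hand-written TPM matrix over the five study tissues.

    GENE_B is GENE_A scaled by 0.5 (identical profile); GENE_Z is
    identically zero and must be removed by the zero-mean filter.
    """
    df = pd.DataFrame(
        {
            "pistil_st11": [12.0, 6.0, 80.0, 1.0, 0.0],
            "pistil_st12": [30.0, 15.0, 20.0, 1.2, 0.0],
            "anther_st12": [2.0, 1.0, 400.0, 0.9, 0.0],
            "pistil_st14": [25.0, 12.5, 15.0, 1.1, 0.0],
            "silique_st17": [6.0, 3.0, 10.0, 1.0, 0.0],
        },
        index=pd.Index(
            ["GENE_A", "GENE_B", "GENE_C", "GENE_D", "GENE_Z"], name="gene_id"
        ),
    )
    return ExpressionMatrix(df)


def random_positive_matrix(
    n_genes: int, n_samples: int, seed: int
) -> ExpressionMatrix:
    """Strictly positive log-normal TPM matrix for property tests."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n_genes, n_samples))
    df = pd.DataFrame(
        values,
        index=pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(df)
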