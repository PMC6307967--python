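import numpy as np
import pandas as pd
import pytest

from episig.expr_io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_log2_matrix():
    values = pd.DataFrame(
        [[5.0, 6.0, 7.0], [8.0, 8.0, 8.0], [2.0, 4.0, 6.0]],
        index=["GENEA", "GENEB", "GENEC"],
        columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values, "log2")


def random_matrix(rng, n_genes=50, n_samples=20, scale="log2"):
    values = pd.DataFrame(
        rng.normal(7, 2, size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"s{i:02d}" for i in range(n_samples)],
    )
    if scale == "counts":
        values = np.floor(2 ** values.clip(lower=0, upper=16)).astype(float)
    return ExpressionMatrix(values, scale)
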