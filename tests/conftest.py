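import numpy as np
import pandas as pd
import pytest

from transcoex.matrix import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, batches=None, classes=None):
    """Build an ExpressionMatrix from a plain array with minimal metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i:02d}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{i:02d}" for i in range(n_samples)]
    batches = batches or ["b0"] * n_samples
    classes = classes or ["CTRL"] * n_samples
    meta = pd.DataFrame(
        {"batch": batches, "class": classes}, index=pd.Index(sample_ids, name="sample_id")
    )
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
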