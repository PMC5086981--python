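import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pairdiff import LINEAR, LOG2, ExpressionDataset

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_dataset(values, scale=LINEAR, labels=None, genes=None, samples=None):
    """Small helper to assemble an ExpressionDataset from a plain array."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i:03d}" for i in range(n_genes)]
    samples = samples or [f"s{j:03d}" for j in range(n_samples)]
    if labels is None:
        half = n_samples // 2
        labels = ["N"] * half + ["C"] * (n_samples - half)
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                         columns=pd.Index(samples, name="sample_id"))
    return ExpressionDataset(frame, scale, pd.Series(list(labels), index=frame.columns))


@pytest.fixture
def rng():
    return np.random.default_rng(20161031)


@pytest.fixture
def small_linear_dataset(rng):
    """100 genes x 10 samples (5 N + 5 C) of positive linear intensities."""
    return make_dataset(rng.lognormal(5.0, 1.0, (100, 10)))
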