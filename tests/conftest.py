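import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from cernet.expression import ExpressionMatrix
from cernet.synthetic import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240611)


@pytest.fixture(scope="session")
def strong_dataset():
    """One strong-signal synthetic dataset shared across tests."""
    return generate_dataset(SimConfig(seed=11))


def make_matrix(values, gene_class="mRNA", n_tumor=None, transformed=False,
                gene_prefix="G", sample_prefix="S"):
    """Small ExpressionMatrix from a 2-D array; first n_tumor columns are tumor."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    if n_tumor is None:
        n_tumor = n_samples // 2
    genes = [f"{gene_prefix}{i}" for i in range(n_genes)]
    samples = [f"{sample_prefix}{i}" for i in range(n_samples)]
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * (n_samples - n_tumor),
                       index=samples)
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, groups, gene_class, transformed=transformed)


@pytest.fixture
def matrix_factory():
    return make_matrix
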