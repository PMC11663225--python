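import numpy as np
import pandas as pd
import pytest

from apoptosig import synthetic
from apoptosig.diffexpr import CountMatrix


@pytest.fixture(scope="session")
def small_truth():
    """A reduced study: 400 genes, blocks of 30, root seed 7."""
    return synthetic.default_truth(n_genes=400, block_size=30, seed=7)


@pytest.fixture(scope="session")
def small_design():
    return synthetic.default_design(n_replicates=3)


@pytest.fixture(scope="session")
def small_counts(small_truth, small_design):
    cm, gene_truth = synthetic.simulate_counts(small_truth, small_design)
    return cm, gene_truth


@pytest.fixture(scope="session")
def small_annotation(small_truth):
    return synthetic.make_annotation(len(small_truth.genes), n_chroms=3, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_count_matrix(values: np.ndarray, genes=None, conditions=None) -> CountMatrix:
    """Build a CountMatrix from a raw array; one cell line, two groups."""
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    if conditions is None:
        half = n_samples // 2
        conditions = ["DMSO"] * half + ["TGFB1_MEKI"] * (n_samples - half)
    names = [f"s{j}" for j in range(n_samples)]
    sheet = pd.DataFrame(
        {
            "cell_line": ["L"] * n_samples,
            "treatment": conditions,
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(names, name="sample"),
    )
    return CountMatrix(pd.DataFrame(values, index=genes, columns=names), sheet)
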