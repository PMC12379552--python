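import numpy as np
import pytest
import scipy.sparse as sp

from trseek.sc_data import CountMatrix
from trseek.synthetic_data import SyntheticSpec, generate


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 200-cell, 300-gene simulated cohort shared across unit tests."""
    spec = SyntheticSpec(n_samples=2, cells_per_sample=100, n_genes=300, seed=1)
    return generate(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study conditions: 4 samples x 1,000 cells, 2,000 genes,
    20 planted effect genes."""
    return generate(SyntheticSpec(seed=2))


def make_counts(values, genes=None, barcodes=None, samples=None):
    values = np.asarray(values)
    n_genes, n_cells = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    barcodes = barcodes or [f"BC{i}" for i in range(n_cells)]
    samples = samples or ["S1"] * n_cells
    return CountMatrix(sp.csr_matrix(values), genes, barcodes, samples)
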