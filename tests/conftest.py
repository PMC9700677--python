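import numpy as np
import pandas as pd
import pytest

from stromadev.containers import CountMatrix
from stromadev.simulate import make_atac, make_methylome, make_sc_dataset


@pytest.fixture(scope="session")
def sc_small():
    """Compact bifurcating scRNA dataset shared across tests."""
    return make_sc_dataset(n_cells=600, n_genes=400, branch_sep=2.0, seed=11)


@pytest.fixture(scope="session")
def meth_small():
    return make_methylome(n_cpg=3000, n_dmr=10, delta=0.4, coverage_mean=30, reps_per_group=3, seed=3)


@pytest.fixture(scope="session")
def atac_small():
    return make_atac(n_peaks=800, n_dar=40, fc=4.0, reps=3, seed=5)


def toy_count_matrix(counts, gene_names=None, cell_names=None, **cell_cols):
    counts = np.asarray(counts)
    genes = gene_names or [f"g{i}" for i in range(counts.shape[0])]
    cells = cell_names or [f"c{j}" for j in range(counts.shape[1])]
    return CountMatrix(
        counts,
        pd.DataFrame(index=pd.Index(genes, name="gene")),
        pd.DataFrame(cell_cols, index=pd.Index(cells, name="cell")),
    )
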