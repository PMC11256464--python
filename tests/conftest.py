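import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from clonewatch.clone_cn import CNMatrix
from clonewatch.simulate import SimulationParams, simulate_cells, simulate_truth


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_bins=60, n_clones=3, genes_per_bin=5, n_passages=3,
        cells_per_sample=250, seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_params):
    return simulate_truth(small_params)


@pytest.fixture(scope="session")
def small_dataset(small_truth, small_params):
    cn, adata = simulate_cells(small_truth, small_params)
    return small_truth, cn, adata


@pytest.fixture
def toy_cn():
    """Five cells, two clones, four bins on two chromosomes."""
    bins = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "start": [0, 500_000, 1_000_000, 0],
            "end": [500_000, 1_000_000, 1_500_000, 500_000],
        }
    )
    copy = pd.DataFrame(
        [[2, 2, 4, 2], [2, 2, 4, 2], [2, 2, 4, 3], [2, 4, 2, 2], [2, 4, 2, 2]],
        index=[f"c{i}" for i in range(5)],
        columns=range(4),
    )
    clone = pd.Series(["A", "A", "A", "B", "B"], index=copy.index)
    return CNMatrix(bins=bins, copy=copy, clone=clone)


def make_counts_adata(X, var_names=None, obs=None):
    X = np.asarray(X)
    var_names = var_names or [f"g{i}" for i in range(X.shape[1])]
    adata = AnnData(
        X=X,
        var=pd.DataFrame(index=pd.Index(var_names, name="gene_id")),
        obs=obs if obs is not None else pd.DataFrame(
            index=pd.Index([f"c{i}" for i in range(X.shape[0])], name="cell_id")
        ),
    )
    return adata
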