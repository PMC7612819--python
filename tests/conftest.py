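import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from devimmune import neighborhoods, syndata

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cells() -> ad.AnnData:
    """A small multi-sample cell table with genes, for preprocessing tests."""
    cfg = syndata.SimConfig(
        seed=7, n_donors=4, n_organs=2, n_celltypes=4, n_genes=300, cells_per_sample=200
    )
    return syndata.generate_cell_dataset(cfg)


@pytest.fixture(scope="session")
def blob_embedding():
    """Two well-separated Gaussian blobs with labels, 600 cells."""
    rng = np.random.default_rng(3)
    n = 600
    labels = rng.integers(0, 2, size=n)
    centers = np.zeros((2, 5))
    centers[1, 0] = 8.0
    emb = centers[labels] + rng.normal(size=(n, 5))
    return emb, labels


@pytest.fixture()
def tiny_nhoods():
    """Two hand-built neighborhoods over five cells: {c0,c1,c2} and {c2,c3}."""
    membership = sparse.csr_matrix(
        np.array([[1, 1, 1, 0, 0], [0, 0, 1, 1, 0]], dtype=bool)
    )
    return neighborhoods.NeighborhoodSet(
        index_cells=np.array([0, 3]),
        membership=membership,
        kth_nn_distance=np.array([1.0, 1.0]),
    )


def make_cells_from_obs(obs: pd.DataFrame, n_genes: int = 0) -> ad.AnnData:
    X = sparse.csr_matrix((len(obs), n_genes))
    return ad.AnnData(X=X, obs=obs)
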