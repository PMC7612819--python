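"""KNN graph, index-cell neighborhoods, sample counts and FACS covariates.

Differential abundance is tested on *neighborhoods*: the sets of cells
adjacent to sampled index cells on a KNN graph built over a latent
embedding.  This module builds the graph (Euclidean, symmetrized by
union), samples and refines index cells, counts member cells per sample,
labels neighborhoods by majority vote, and computes the per-sample FACS
correction covariate used to absorb CD45-sorting enrichment in the count
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "KNNGraph",
    "NeighborhoodSet",
    "NhoodCounts",
    "build_knn",
    "make_neighborhoods",
    "count_cells_by_sample",
    "label_neighborhoods",
    "facs_correction_factor",
]


@dataclass
class KNNGraph:
    """Directed k-NN relation plus its union-symmetrized adjacency."""

    indices: np.ndarray  # (n, k) neighbor indices, self excluded
    distances: np.ndarray  # (n, k) matching Euclidean distances
    adjacency: sparse.csr_matrix  # symmetric boolean, no self loops
    k: int


@dataclass
class NeighborhoodSet:
    index_cells: np.ndarray  # (n_nhoods,) cell indices
    membership: sparse.csr_matrix  # (n_nhoods, n_cells) boolean
    kth_nn_distance: np.ndarray  # (n_nhoods,) distance from index cell to kth NN


@dataclass
class NhoodCounts:
    counts: pd.DataFrame  # neighborhoods × samples, integer
    sample_meta: pd.DataFrame  # indexed by sample_id
    labels: pd.Series | None = None  # per-neighborhood cell-type label


def build_knn(embedding: np.ndarray, k: int) -> KNNGraph:
    """Exact Euclidean k-NN graph, symmetrized by union.

    Ties in distance are broken by cell index (stable order).  ``k`` must
    be positive and smaller than the number of cells.
    """
    emb = np.asarray(embedding, dtype=float)
    if not np.isfinite(emb).all():
        raise ValueError("embedding contains non-finite values")
    n = emb.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto", metric="euclidean")
    nn.fit(emb)
    dist, idx = nn.kneighbors(emb)
    # drop self (distance 0 at its own index); with exact duplicates the
    # self column may not come first, so remove by index match instead
    out_idx = np.empty((n, k), dtype=np.int64)
    out_dist = np.empty((n, k))
    for i in range(n):
        row = idx[i]
        pos = np.where(row == i)[0]
        keep = np.delete(np.arange(k + 1), pos[0] if pos.size else k)[:k]
        out_idx[i] = row[keep]
        out_dist[i] = dist[i, keep]
    rows = np.repeat(np.arange(n), k)
    adj = sparse.csr_matrix(
        (np.ones(n * k, dtype=bool), (rows, out_idx.ravel())), shape=(n, n)
    )
    adj = (adj + adj.T).astype(bool)
    adj.setdiag(False)
    adj.eliminate_zeros()
    return KNNGraph(indices=out_idx, distances=out_dist, adjacency=adj, k=k)


def make_neighborhoods(
    graph: KNNGraph, embedding: np.ndarray, prop: float = 0.05, seed: int = 0
) -> NeighborhoodSet:
    """Sample index cells and refine them to yield neighborhoods.

    ``ceil(prop * n)`` cells are sampled uniformly without replacement;
    each is refined to the member of its (closed) graph neighborhood
    nearest to the neighborhood's componentwise median embedding
    position, then duplicates are removed.  Each neighborhood is the
    refined index cell plus its symmetrized graph neighbors.
    """
    if not 0 < prop <= 1:
        raise ValueError("prop must be in (0, 1]")
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    n_sample = int(np.ceil(prop * n))
    if n_sample < 1:
        raise ValueError("prop * n_cells < 1")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(n, size=n_sample, replace=False)

    adj = graph.adjacency
    refined = np.empty(n_sample, dtype=np.int64)
    for j, i in enumerate(sampled):
        members = np.append(adj[i].indices, i)
        median = np.median(emb[members], axis=0)
        d = np.linalg.norm(emb[members] - median, axis=1)
        refined[j] = members[np.argmin(d)]
    index_cells = np.unique(refined)

    rows, cols = [], []
    for r, i in enumerate(index_cells):
        members = np.append(adj[i].indices, i)
        rows.extend([r] * members.size)
        cols.extend(members.tolist())
    membership = sparse.csr_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)),
        shape=(index_cells.size, n),
    )
    kth = graph.distances[index_cells, -1]
    return NeighborhoodSet(index_cells=index_cells, membership=membership, kth_nn_distance=kth)


_SAMPLE_META_COLS = ["donor_id", "organ", "age_pcw", "sort_fraction"]


def count_cells_by_sample(nhoods: NeighborhoodSet, cells: ad.AnnData) -> NhoodCounts:
    """Count member cells of each neighborhood per sample.

    ``counts[i, s]`` is the number of cells of sample ``s`` belonging to
    neighborhood ``i``; sample metadata (donor, organ, age, sort
    fraction) is carried over from the cell table.
    """
    obs = cells.obs
    if "sample_id" not in obs:
        raise ValueError("cells must carry a sample_id column")
    samples = pd.Categorical(obs["sample_id"])
    onehot = sparse.csr_matrix(
        (
            np.ones(len(obs), dtype=np.int64),
            (np.arange(len(obs)), samples.codes),
        ),
        shape=(len(obs), len(samples.categories)),
    )
    counts = np.asarray((nhoods.membership.astype(np.int64) @ onehot).todense())
    counts_df = pd.DataFrame(counts, columns=samples.categories)
    meta_cols = [c for c in _SAMPLE_META_COLS if c in obs.columns]
    meta = obs.groupby("sample_id", observed=True)[meta_cols].first()
    meta["total_cells"] = obs.groupby("sample_id", observed=True).size()
    meta = meta.loc[counts_df.columns]
    return NhoodCounts(counts=counts_df, sample_meta=meta)


def label_neighborhoods(nhoods: NeighborhoodSet, cell_labels: pd.Series | np.ndarray) -> pd.Series:
    """Majority-vote neighborhood labels.

    The modal member label is assigned when it is unique and covers at
    least 50% of member cells; otherwise the neighborhood is "Mixed"
    (including exact ties between modes).
    """
    labels = np.asarray(cell_labels, dtype=object)
    cats, codes = np.unique(labels, return_inverse=True)
    onehot = sparse.csr_matrix(
        (np.ones(labels.size, dtype=np.int64), (np.arange(labels.size), codes)),
        shape=(labels.size, cats.size),
    )
    tab = np.asarray((nhoods.membership.astype(np.int64) @ onehot).todense())
    sizes = tab.sum(axis=1)
    if (sizes == 0).any():
        raise ValueError("empty neighborhood")
    top = tab.max(axis=1)
    is_tie = (tab == top[:, None]).sum(axis=1) > 1
    share = top / sizes
    modal = cats[np.argmax(tab, axis=1)]
    out = np.where((share >= 0.5) & ~is_tie, modal, "Mixed")
    return pd.Series(out, name="nhood_label")


def facs_correction_factor(
    sample_meta: pd.DataFrame, facs_proportions: dict[str, float] | pd.Series | None = None
) -> pd.Series:
    """Per-sample FACS correction covariate.

    Unsorted samples get 0.  A FACS-sorted fraction with measured
    live-cell share pi gets ln(pi), so the count model can absorb the
    enrichment that sorting introduces.  A sorted sample with no recorded
    proportion is an error.
    """
    facs_proportions = dict(facs_proportions or {})
    out = np.zeros(len(sample_meta))
    for i, (sid, row) in enumerate(sample_meta.iterrows()):
        frac = row.get("sort_fraction", "unsorted")
        if frac == "unsorted":
            continue
        if sid not in facs_proportions:
            raise ValueError(f"sorted sample {sid!r} has no recorded live-cell proportion")
        pi = facs_proportions[sid]
        if not 0 < pi <= 1:
            raise ValueError(f"live-cell proportion for {sid!r} outside (0, 1]")
        out[i] = np.log(pi)
    return pd.Series(out, index=sample_meta.index, name="facs_factor")
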