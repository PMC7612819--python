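"""Gaussian-kernel KNN label transfer and NMI labeling agreement.

Query cells are mapped onto reference labels through a joint embedding:
each query's k nearest reference cells vote with Gaussian weights
``exp(-d^2 / (2 sigma^2))`` where the bandwidth sigma is the query's
kth-neighbor distance, and the normalized per-label weight sums give a
similarity score; the argmax label is predicted.  Agreement between two
labelings is scored with normalized mutual information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_gaussian_label_transfer", "nmi_score"]


def knn_gaussian_label_transfer(
    query_embedding: np.ndarray,
    ref_embedding: np.ndarray,
    ref_labels: np.ndarray | pd.Series,
    k: int = 30,
) -> pd.DataFrame:
    """Predict query labels by Gaussian-weighted reference neighbors.

    Returns a frame with one row per query cell: the predicted label,
    its score, the distance to the nearest reference cell, and one score
    column per label (scores sum to 1 per cell).
    """
    Q = np.asarray(query_embedding, dtype=float)
    R = np.asarray(ref_embedding, dtype=float)
    labels = np.asarray(ref_labels, dtype=object)
    if R.shape[0] == 0:
        raise ValueError("empty reference")
    if k <= 0:
        raise ValueError("k must be positive")
    if k > R.shape[0]:
        raise ValueError("k exceeds the reference size")
    if Q.shape[1] != R.shape[1]:
        raise ValueError("query and reference embeddings must share dimensionality")

    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(R)
    dist, idx = nn.kneighbors(Q)
    sigma = dist[:, -1][:, None]
    sigma = np.where(sigma <= 0, 1.0, sigma)  # all-coincident neighbors
    w = np.exp(-(dist**2) / (2.0 * sigma**2))

    cats = np.unique(labels)
    scores = np.zeros((Q.shape[0], cats.size))
    code = {c: j for j, c in enumerate(cats)}
    neigh_codes = np.vectorize(code.get)(labels[idx])
    for j in range(cats.size):
        scores[:, j] = np.where(neigh_codes == j, w, 0.0).sum(axis=1)
    scores /= scores.sum(axis=1, keepdims=True)

    pred = cats[np.argmax(scores, axis=1)]
    out = pd.DataFrame(
        {
            "predicted_label": pred,
            "top_score": scores.max(axis=1),
            "nearest_distance": dist[:, 0],
        }
    )
    for j, c in enumerate(cats):
        out[f"score_{c}"] = scores[:, j]
    return out


def nmi_score(labels_a, labels_b, average_method: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings, in [0, 1].

    Normalization divides mutual information by the arithmetic mean of
    the two entropies (a geometric-mean variant is available).  If either
    labeling has a single class the score is defined as 0, with a
    warning, since 0/0 is otherwise undefined.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size == 0:
        raise ValueError("empty labelings")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        warnings.warn("single-class labeling; NMI defined as 0", stacklevel=2)
        return 0.0
    # canonicalize the argument order so nmi(a, b) == nmi(b, a) bit-exactly
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    if cb.tobytes() < ca.tobytes():
        ca, cb = cb, ca
    return float(normalized_mutual_info_score(ca, cb, average_method=average_method))
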