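"""Colocalization microenvironments from spot × cell-type abundances.

Estimated cell-type abundances on spatial-transcriptomics spots are
factorized with nonnegative matrix factorization (d factors, default 10);
each latent factor is read as a tissue microenvironment defined by the
cell types whose across-factor loading fraction exceeds 0.2.  Cell types
never reaching the detection threshold (0.15 at the 99% abundance
quantile) in any slide are excluded first.  Spots are assigned to a
microenvironment when their factor weight exceeds the slide's 90%
quantile; factors can be pre-selected by requiring a cell-type group
(e.g., mature T cells) to account for more than 0.8 of loading fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

__all__ = [
    "MicroenvironmentSet",
    "filter_detected_types",
    "factorize_nmf",
    "microenvironment_membership",
    "assign_spots_to_microenv",
]


@dataclass
class MicroenvironmentSet:
    W: pd.DataFrame  # spots × factors
    H: pd.DataFrame  # factors × celltypes
    H_norm: pd.DataFrame  # H with each celltype column normalized to sum 1 over factors
    d: int
    reconstruction_error: float


def filter_detected_types(
    abundance: pd.DataFrame,
    slide_ids: pd.Series,
    q: float = 0.99,
    threshold: float = 0.15,
) -> list[str]:
    """Cell types whose q-quantile abundance reaches the threshold somewhere.

    A cell type is excluded only if its ``q``-quantile abundance is below
    ``threshold`` in *every* slide.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    keep = []
    excluded = []
    for ct in abundance.columns:
        detected = False
        for _, idx in abundance.groupby(slide_ids.to_numpy(), observed=True).groups.items():
            if np.quantile(abundance.loc[idx, ct], q) >= threshold:
                detected = True
                break
        (keep if detected else excluded).append(ct)
    if not keep:
        raise ValueError("all cell types fall below the detection threshold")
    if excluded:
        warnings.warn(f"excluding undetected cell types: {excluded}", stacklevel=2)
    return keep


def factorize_nmf(abundance: pd.DataFrame, d: int = 10, seed: int = 0) -> MicroenvironmentSet:
    """NMF of the abundance matrix into d microenvironment factors.

    Uses nonnegative-double-SVD initialization (deterministic given the
    seed) and coordinate-descent minimization of the Frobenius
    reconstruction error.
    """
    A = abundance.to_numpy(dtype=float)
    if (A < 0).any():
        raise ValueError("abundances must be nonnegative")
    if d <= 0:
        raise ValueError("d must be positive")
    if d >= min(A.shape):
        raise ValueError("d must be smaller than both matrix dimensions")
    model = NMF(
        n_components=d,
        init="nndsvda",
        solver="cd",
        max_iter=2000,
        tol=1e-6,
        random_state=seed,
    )
    W = model.fit_transform(A)
    H = model.components_
    factors = [f"factor_{k}" for k in range(d)]
    W_df = pd.DataFrame(W, index=abundance.index, columns=factors)
    H_df = pd.DataFrame(H, index=factors, columns=abundance.columns)
    colsum = H_df.sum(axis=0).replace(0, np.nan)
    H_norm = H_df.div(colsum, axis=1).fillna(0.0)
    return MicroenvironmentSet(
        W=W_df,
        H=H_df,
        H_norm=H_norm,
        d=d,
        reconstruction_error=float(model.reconstruction_err_),
    )


def microenvironment_membership(
    me: MicroenvironmentSet,
    frac_threshold: float = 0.2,
    group: list[str] | None = None,
    group_sum_threshold: float = 0.8,
) -> dict:
    """Cell-type membership per factor, with optional group-based retention.

    A cell type belongs to a factor iff its across-factor loading
    fraction is strictly over ``frac_threshold``.  When ``group`` is
    given, only factors whose summed fractions over the group strictly
    exceed ``group_sum_threshold`` are retained.
    """
    membership = {
        f: sorted(me.H_norm.columns[me.H_norm.loc[f] > frac_threshold])
        for f in me.H_norm.index
    }
    retained = list(me.H_norm.index)
    if group is not None:
        gcols = [c for c in group if c in me.H_norm.columns]
        sums = me.H_norm[gcols].sum(axis=1)
        retained = list(sums.index[sums > group_sum_threshold])
    return {"membership": membership, "retained_factors": retained}


def assign_spots_to_microenv(
    me: MicroenvironmentSet, slide_ids: pd.Series, q: float = 0.90
) -> pd.DataFrame:
    """Boolean spot × factor assignment by per-slide weight quantile.

    A spot carries a factor when its weight is strictly above the ``q``
    quantile of that factor's weights within the spot's slide; a spot may
    carry several factors, constant-weight slides assign none.
    """
    slide = np.asarray(slide_ids)
    out = pd.DataFrame(False, index=me.W.index, columns=me.W.columns)
    for s in np.unique(slide):
        mask = slide == s
        if mask.sum() < 10:
            warnings.warn(f"slide {s!r} has fewer than 10 spots; quantile unstable", stacklevel=2)
        sub = me.W.loc[mask]
        cut = sub.quantile(q, axis=0)
        out.loc[mask] = (sub > cut).to_numpy()
    return out
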