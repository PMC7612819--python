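"""Pseudobulk aggregation and the organ × cell-type interaction NB-GLM.

Single-cell raw counts are summed per (sample, cell type) into pseudobulk
profiles.  Counts of gene g in pseudobulk p are modeled as
``NB(mu_gp, phi_gp)`` with

    log mu_gp = b0 + d_p b_donor + o_p b_organ + c_p b_celltype
                + c_p o_p b_organ_x_celltype + log L_p

where ``o_p``/``c_p`` indicate the target organ/cell type and ``L_p`` is
the pseudobulk library size.  The interaction coefficient is the organ-
specific log fold change within the target cell type; inference uses the
quasi-likelihood route shared with the differential-abundance model.
Repeating the fit with control cell types as the "target" flags genes
whose apparent organ specificity is a shared technical effect of tissue
processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from statsmodels.stats.multitest import multipletests

from ._nbglm import fit_nbglm_many

__all__ = [
    "PseudobulkMatrix",
    "aggregate_pseudobulk",
    "fit_interaction_nbglm",
    "filter_by_control_types",
]


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame  # genes × pseudobulks, integer sums of member-cell counts
    meta: pd.DataFrame  # per-pseudobulk donor, organ, celltype, n_cells, library_size


def aggregate_pseudobulk(
    cells: ad.AnnData,
    min_cells: int = 20,
    sample_key: str = "sample_id",
    celltype_key: str = "celltype_label",
    layer: str | None = "counts",
) -> PseudobulkMatrix:
    """Sum raw counts into one pseudobulk per (sample, cell type).

    Groups with fewer than ``min_cells`` cells are dropped (reported in
    ``meta.attrs["dropped"]``).  ``layer`` selects where raw counts live;
    ``None`` uses ``X``.
    """
    X = cells.layers[layer] if layer and layer in cells.layers else cells.X
    obs = cells.obs
    key = obs[sample_key].astype(str) + "|" + obs[celltype_key].astype(str)
    groups = pd.Categorical(key)
    onehot = sparse.csr_matrix(
        (np.ones(len(obs)), (groups.codes, np.arange(len(obs)))),
        shape=(len(groups.categories), len(obs)),
    )
    sums = onehot @ (X if sparse.issparse(X) else np.asarray(X))
    sums = np.asarray(sums.todense() if sparse.issparse(sums) else sums)
    sizes = np.asarray(onehot.sum(axis=1)).ravel().astype(int)

    keep = sizes >= min_cells
    dropped = [str(groups.categories[i]) for i in np.where(~keep)[0]]
    if not keep.any():
        raise ValueError(f"no (sample, celltype) group reaches min_cells={min_cells}")

    meta_rows = []
    for gi in np.where(keep)[0]:
        sample_id, celltype = str(groups.categories[gi]).split("|", 1)
        sub = obs[key == groups.categories[gi]].iloc[0]
        meta_rows.append(
            {
                "pseudobulk_id": str(groups.categories[gi]),
                "sample_id": sample_id,
                "donor": str(sub.get("donor_id", sub.get("donor", sample_id))),
                "organ": str(sub.get("organ", "NA")),
                "celltype": celltype,
                "n_cells": int(sizes[gi]),
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("pseudobulk_id")
    counts = pd.DataFrame(
        np.rint(sums[keep]).astype(np.int64).T,
        index=cells.var_names,
        columns=meta.index,
    )
    meta["library_size"] = counts.sum(axis=0)
    meta.attrs["dropped"] = dropped
    return PseudobulkMatrix(counts=counts, meta=meta)


def _interaction_design(
    meta: pd.DataFrame, target_organ: str, target_celltype: str
) -> tuple[np.ndarray, list[str]]:
    """Interaction design in its per-cell-type parametrization.

    The organ effect is split into ``organ_other`` (target organ in
    non-target cell types) and ``organ_in_celltype`` (target organ in the
    target cell type).  This spans the same column space as the classic
    main-effect + interaction coding, but the ``organ_in_celltype``
    coefficient is directly the organ log fold change experienced by the
    target cell type — the quantity tested and compared against control
    cell types — while the classic interaction coefficient is recovered
    as the difference of the two organ columns.
    """
    organ_ind = (meta["organ"] == target_organ).astype(float).to_numpy()
    ct_ind = (meta["celltype"] == target_celltype).astype(float).to_numpy()
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    donor_d = pd.get_dummies(meta["donor"], drop_first=True)
    for c in donor_d.columns:
        cols.append(donor_d[c].to_numpy(dtype=float))
        names.append(f"donor[{c}]")
    cols += [organ_ind * (1.0 - ct_ind), ct_ind, organ_ind * ct_ind]
    names += ["organ_other", "celltype", "organ_in_celltype"]
    return np.column_stack(cols), names


def fit_interaction_nbglm(
    pb: PseudobulkMatrix,
    target_organ: str,
    target_celltype: str,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-gene interaction NB-GLM with log library-size offset.

    Returns a frame with, per gene: ``logFC`` — the organ log fold change
    experienced by the target cell type (the tested coefficient, also the
    one compared against control cell types); ``interaction_logFC`` — the
    classic organ × cell-type interaction coefficient (how much the
    target cell type's organ effect exceeds the other cell types'); the
    quasi-likelihood p-value, BH FDR and a convergence flag.
    """
    meta = pb.meta
    if meta["organ"].nunique() < 2 or meta["celltype"].nunique() < 2:
        raise ValueError("interaction model needs >=2 organs and >=2 cell types")
    if meta["donor"].nunique() < 2:
        raise ValueError("interaction model needs >=2 donors")
    X, names = _interaction_design(meta, target_organ, target_celltype)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient interaction design")
    Y = pb.counts.to_numpy(dtype=float)
    offset = np.log(meta["library_size"].to_numpy(dtype=float))

    expressed = Y.sum(axis=1) > 0
    res = fit_nbglm_many(Y[expressed], X, offset, prior_df=prior_df)
    ci = names.index("organ_in_celltype")
    co = names.index("organ_other")

    out = pd.DataFrame(
        {
            "gene": pb.counts.index,
            "logFC": np.nan,
            "interaction_logFC": np.nan,
            "se": np.nan,
            "pval": np.nan,
            "converged": False,
        }
    ).set_index("gene")
    out.loc[expressed, "logFC"] = res.coef[:, ci]
    out.loc[expressed, "interaction_logFC"] = res.coef[:, ci] - res.coef[:, co]
    out.loc[expressed, "se"] = res.se[:, ci]
    out.loc[expressed, "pval"] = res.pvalues[:, ci]
    out.loc[expressed, "converged"] = res.converged
    fdr = np.full(len(out), np.nan)
    fdr[expressed] = multipletests(out.loc[expressed, "pval"], method="fdr_bh")[1]
    out["FDR"] = fdr
    out.attrs["target_organ"] = target_organ
    out.attrs["target_celltype"] = target_celltype
    return out.reset_index()


def filter_by_control_types(
    fit: pd.DataFrame,
    control_fits: list[pd.DataFrame],
    lfc_threshold: float = 0.5,
    control_fdr: float = 0.1,
) -> pd.DataFrame:
    """Flag genes whose organ effect reappears in control cell types.

    A gene is marked ``technical`` when any control fit (the same organ
    contrast run with a control cell type as target) shows a same-sign
    logFC of magnitude at least ``lfc_threshold`` at FDR below
    ``control_fdr``.  The returned frame adds the flag; callers keep the
    non-technical rows.
    """
    if not control_fits:
        raise ValueError("at least one control cell-type fit is required")
    out = fit.copy()
    technical = np.zeros(len(out), dtype=bool)
    sign = np.sign(out["logFC"].to_numpy())
    for ctrl in control_fits:
        c = ctrl.set_index("gene").reindex(out["gene"])
        same_sign = np.sign(c["logFC"].to_numpy()) == sign
        strong = np.abs(c["logFC"].to_numpy()) >= lfc_threshold
        sig = c["FDR"].to_numpy() < control_fdr
        technical |= np.nan_to_num(same_sign & strong & sig).astype(bool)
    out["technical"] = technical
    return out
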