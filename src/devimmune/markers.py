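"""DA-guided marker discovery and gene-set activation scoring.

Once differential abundance identifies stage- or organ-specific
neighborhoods for a cell type, markers are found by testing cells of that
type in the significant neighborhoods against the type's remaining cells,
using the overestimated-variance t-test; candidate markers are then
filtered by expressed fraction, effect size and FDR.  Gene-set activation
scores follow the control-gene-bin convention: the mean normalized-log
expression of the set minus the mean of expression-matched control genes.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .datest import DAResult
from .neighborhoods import NeighborhoodSet

__all__ = [
    "select_da_cells",
    "rank_genes_welch_t",
    "filter_markers",
    "score_gene_set",
]


def select_da_cells(
    da: DAResult,
    nhoods: NeighborhoodSet,
    cell_labels: np.ndarray | pd.Series,
    celltype: str,
    direction: str,
    fdr_threshold: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a cell type's cells by membership in significant neighborhoods.

    Set A collects cells of ``celltype`` belonging to at least one
    significant neighborhood of the requested ``direction`` ("early":
    logFC < 0; "late": logFC > 0) labeled ``celltype``; set B collects
    the type's cells from all other neighborhoods.  A cell in both goes
    to A, keeping the two-sample test disjoint.  Returns boolean masks
    (setA, setB) over cells.
    """
    if direction not in {"early", "late"}:
        raise ValueError("direction must be 'early' or 'late'")
    tab = da.table
    sig = tab["spatial_fdr"] < fdr_threshold
    sig &= tab["logFC"] < 0 if direction == "early" else tab["logFC"] > 0
    if "label" in tab.columns:
        sig &= tab["label"] == celltype
    sig = sig.fillna(False).to_numpy()
    if not sig.any():
        warnings.warn(f"no significant {direction} neighborhoods for {celltype!r}", stacklevel=2)

    labels = np.asarray(cell_labels, dtype=object)
    memb = nhoods.membership
    in_sig = np.asarray(memb[sig].sum(axis=0)).ravel() > 0
    in_any = np.asarray(memb.sum(axis=0)).ravel() > 0
    is_type = labels == celltype
    setA = is_type & in_sig
    setB = is_type & in_any & ~in_sig
    return setA, setB


def _group_stats(X, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    sub = X[mask]
    n = int(mask.sum())
    if sparse.issparse(sub):
        mean = np.asarray(sub.mean(axis=0)).ravel()
        sq = np.asarray(sub.multiply(sub).mean(axis=0)).ravel()
    else:
        mean = sub.mean(axis=0)
        sq = (np.asarray(sub) ** 2).mean(axis=0)
    var = np.maximum((sq - mean**2) * n / max(n - 1, 1), 0.0)
    return mean, var, n


def rank_genes_welch_t(
    norm: ad.AnnData | np.ndarray,
    setA: np.ndarray,
    setB: np.ndarray,
    var_names: pd.Index | None = None,
) -> pd.DataFrame:
    """Overestimated-variance t-test of group A versus group B per gene.

    The statistic is ``t = (m_A - m_B) / sqrt(v_A/n_A + v_B/n_A)`` — both
    variance terms are divided by the group-A size, a deliberately
    conservative variant of Welch's test — with two-sided p-values from
    the t distribution (Welch–Satterthwaite df on the same overestimated
    terms) and BH-adjusted FDR.  Genes with zero variance in both groups
    get p = 1.
    """
    if isinstance(norm, ad.AnnData):
        X = norm.X
        names = norm.var_names
    else:
        X = norm
        names = var_names if var_names is not None else pd.RangeIndex(np.shape(norm)[1]).astype(str)
    setA = np.asarray(setA, dtype=bool)
    setB = np.asarray(setB, dtype=bool)
    if setA.sum() < 2 or setB.sum() < 2:
        raise ValueError("both groups need at least 2 cells")
    mA, vA, nA = _group_stats(X, setA)
    mB, vB, _nB = _group_stats(X, setB)
    denom_sq = vA / nA + vB / nA
    logfc = mA - mB
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(denom_sq)
        df = denom_sq**2 / ((vA / nA) ** 2 / (nA - 1) + (vB / nA) ** 2 / (nA - 1))
    zerovar = denom_sq == 0
    t = np.where(zerovar, 0.0, t)
    df = np.where(zerovar | ~np.isfinite(df), 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zerovar, 1.0, np.clip(p, 0.0, 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]

    expr_frac = _expressed_fraction(X, setA | setB)
    return pd.DataFrame(
        {
            "gene": np.asarray(names, dtype=object),
            "logFC": logfc,
            "t": t,
            "pval": p,
            "FDR": fdr,
            "expr_fraction": expr_frac,
        }
    )


def _expressed_fraction(X, mask: np.ndarray) -> np.ndarray:
    sub = X[mask]
    if sparse.issparse(sub):
        return np.asarray((sub > 0).mean(axis=0)).ravel()
    return (np.asarray(sub) > 0).mean(axis=0)


def filter_markers(
    de: pd.DataFrame,
    max_expr_fraction: float = 0.7,
    min_logfc: float = 1.0,
    max_fdr: float = 1e-3,
) -> pd.DataFrame:
    """Apply the marker filter chain.

    Keeps genes expressed in at most 70% of tested cells, with logFC > 1
    and FDR < 0.1%.  The output is invariant to gene order, and relaxing
    any threshold can only grow the list.
    """
    keep = (
        (de["expr_fraction"] <= max_expr_fraction)
        & (de["logFC"] > min_logfc)
        & (de["FDR"] < max_fdr)
    )
    return de[keep].reset_index(drop=True)


def score_gene_set(
    norm: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 25,
    n_control: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched gene-set activation score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of mean
    normalized-log expression; for each set gene, ``n_control`` control
    genes are sampled from its bin, and the score is the mean expression
    of the set minus the mean expression of the control pool.  Set genes
    absent from the matrix are dropped with a report; an empty
    intersection is an error.  Deterministic under ``seed``.
    """
    names = np.asarray(norm.var_names, dtype=object)
    present = [g for g in gene_set if g in set(names)]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        warnings.warn(f"dropping {len(missing)} gene(s) absent from the matrix", stacklevel=2)
    if not present:
        raise ValueError("gene set empty after intersecting with the matrix")
    X = norm.X
    mean = (
        np.asarray(X.mean(axis=0)).ravel() if sparse.issparse(X) else np.asarray(X).mean(axis=0)
    )
    order = np.argsort(mean, kind="stable")
    bins = np.empty(names.size, dtype=int)
    bins[order] = np.arange(names.size) * n_bins // names.size

    rng = np.random.default_rng(seed)
    set_idx = np.array([int(np.where(names == g)[0][0]) for g in present])
    control: set[int] = set()
    for gi in set_idx:
        pool = np.where(bins == bins[gi])[0]
        take = min(n_control, pool.size)
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(control))

    def _mean_over(idx: np.ndarray) -> np.ndarray:
        sub = X[:, idx]
        if sparse.issparse(sub):
            return np.asarray(sub.mean(axis=1)).ravel()
        return np.asarray(sub).mean(axis=1)

    return _mean_over(set_idx) - _mean_over(ctrl_idx)
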