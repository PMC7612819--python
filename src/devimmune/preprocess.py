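"""Cell-level QC, depth normalization and highly-variable-gene selection.

The constants mirror a standard droplet scRNA-seq workflow: cells with
fewer than 2,000 total reads or 500 detected genes are discarded, counts
are scaled to a common per-cell total and ln(x+1)-transformed, and genes
are ranked by normalized dispersion within a mean-expression window
(0.001–10) to pick the top highly variable genes, excluding cell-cycle and
TCR/BCR genes that would otherwise dominate an immune atlas embedding.
"""

from __future__ import annotations

import re
import warnings
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "qc_filter",
    "normalize_log",
    "select_hvg",
    "default_exclusion_genes",
    "TCR_BCR_PATTERN",
]

# V(D)J-rearranging receptor loci: TR[ABGD] and IG[HKL] variable/joining/
# diversity/constant segment symbols
TCR_BCR_PATTERN = re.compile(r"^(TR[ABGD][VDJC]|IG[HKL][VDJCG])")


def default_exclusion_genes(var_names: pd.Index) -> list[str]:
    """Cell-cycle genes (shipped list) plus TCR/BCR genes matched by symbol."""
    with resources.files("devimmune.data").joinpath("cell_cycle_genes.txt").open() as fh:
        cc = {line.strip() for line in fh if line.strip()}
    out = [g for g in var_names if g in cc or TCR_BCR_PATTERN.match(g)]
    return out


def _totals(X) -> tuple[np.ndarray, np.ndarray]:
    if sparse.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        ngenes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        total = X.sum(axis=1)
        ngenes = (X > 0).sum(axis=1)
    return total, ngenes


def qc_filter(cells: ad.AnnData, min_reads: int = 2000, min_genes: int = 500) -> ad.AnnData:
    """Drop cells below the total-count / detected-gene thresholds.

    Cell order is preserved.  An empty result is returned with a warning
    rather than raised as an error.
    """
    if min_reads < 0 or min_genes < 0:
        raise ValueError("thresholds must be nonnegative")
    total, ngenes = _totals(cells.X)
    keep = (total >= min_reads) & (ngenes >= min_genes)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return cells[keep].copy()


def normalize_log(cells: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then apply ln(x+1).

    Raw counts are preserved in ``layers["counts"]``; ``X`` becomes the
    normalized-log matrix.  Cells with zero total counts are an error
    (run :func:`qc_filter` first).
    """
    out = cells.copy()
    X = out.X
    total = np.asarray(X.sum(axis=1)).ravel() if sparse.issparse(X) else X.sum(axis=1)
    zero = np.where(total == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero cell(s): {list(out.obs_names[zero[:5]])}")
    out.layers["counts"] = X.copy()
    scale = target_sum / total
    if sparse.issparse(X):
        X = X.multiply(scale[:, None]).tocsr()
        X.data = np.log1p(X.data)
    else:
        X = np.log1p(X * scale[:, None])
    out.X = X
    return out


def select_hvg(
    norm: ad.AnnData | np.ndarray,
    min_mean: float = 0.001,
    max_mean: float = 10.0,
    n_top: int = 7500,
    exclude: list[str] | None = None,
    n_bins: int = 20,
    var_names: pd.Index | None = None,
) -> list[str]:
    """Select highly variable genes by binned normalized dispersion.

    Genes are ranked by the dispersion statistic variance/mean of the
    normalized-log values, z-scored within ``n_bins`` equal-frequency bins
    of mean expression, restricted to the (min_mean, max_mean) window.
    The top ``n_top`` gene names are returned minus the exclusion list; if
    fewer genes are eligible than requested, all eligible genes are
    returned with a warning.
    """
    if isinstance(norm, ad.AnnData):
        X = norm.X
        names = norm.var_names
    else:
        X = norm
        names = var_names if var_names is not None else pd.RangeIndex(X.shape[1]).astype(str)
    if sparse.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        mean = X.mean(axis=0)
        sq = (np.asarray(X) ** 2).mean(axis=0)
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    eligible = (mean > min_mean) & (mean < max_mean)
    excl = set(exclude or [])
    eligible &= ~np.isin(np.asarray(names, dtype=object), list(excl))
    idx = np.where(eligible)[0]
    if idx.size == 0:
        warnings.warn("no genes eligible for HVG selection", stacklevel=2)
        return []

    # equal-frequency mean bins among eligible genes
    order = np.argsort(mean[idx], kind="stable")
    nb = min(n_bins, idx.size)
    bins = np.empty(idx.size, dtype=int)
    bins[order] = np.arange(idx.size) * nb // idx.size
    z = np.empty(idx.size)
    d = disp[idx]
    for b in np.unique(bins):
        sel = bins == b
        mu_b, sd_b = d[sel].mean(), d[sel].std()
        z[sel] = (d[sel] - mu_b) / sd_b if sd_b > 0 else 0.0

    if n_top >= idx.size:
        if n_top > idx.size:
            warnings.warn(
                f"requested {n_top} HVGs but only {idx.size} eligible", stacklevel=2
            )
        chosen = idx
    else:
        top = np.argsort(-z, kind="stable")[:n_top]
        chosen = idx[top]
    return [str(names[i]) for i in sorted(chosen)]
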