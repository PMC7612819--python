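"""Neighborhood differential-abundance testing with spatial FDR control.

Cell counts per neighborhood and sample are modeled with negative-binomial
log-linear GLMs: a single ordinal slope over gestational-age bins (bin
width 2 pcw by default) or an organ-versus-rest indicator, with the
per-sample FACS correction factor and library-preparation protocol as
confounders and the log total cell count per sample as offset.  Multiple
testing over neighborhoods is controlled with a weighted Benjamini–
Hochberg procedure whose weights are reciprocal kth-nearest-neighbor
distances, so that dense regions of the embedding (many overlapping
neighborhoods) are not penalized for their redundancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nbglm import fit_nbglm_many
from .neighborhoods import NhoodCounts

__all__ = [
    "DAResult",
    "bin_gestational_ages",
    "fit_nhood_glm",
    "spatial_fdr",
    "test_age_trend",
    "test_organ_specificity",
]


@dataclass
class DAResult:
    """Per-neighborhood test output, in the input neighborhood order."""

    table: pd.DataFrame  # columns: nhood_id, label, logFC, pval, spatial_fdr

    def flagged(self, fdr: float = 0.01, positive_only: bool = True) -> pd.Series:
        ok = self.table["spatial_fdr"] < fdr
        if positive_only:
            ok &= self.table["logFC"] > 0
        return ok


def bin_gestational_ages(
    sample_meta: pd.DataFrame, bin_width: float = 2.0, min_consecutive: int = 3
) -> pd.DataFrame:
    """Assign age bins and drop organs with sparse gestational coverage.

    Bins of ``bin_width`` pcw are anchored at the dataset minimum age.
    Organs whose samples do not span at least ``min_consecutive``
    consecutive bins are excluded (their developmental trend cannot be
    estimated) and reported via a warning.
    """
    ages = sample_meta["age_pcw"].to_numpy(dtype=float)
    if (ages <= 0).any():
        raise ValueError("ages must be positive pcw")
    lo = ages.min()
    bins = np.floor((ages - lo) / bin_width).astype(int)
    out = sample_meta.copy()
    out["age_bin"] = bins

    keep_organs = []
    for organ, grp in out.groupby("organ", observed=True):
        present = np.unique(grp["age_bin"])
        run, best = 1, 1
        for a, b in zip(present[:-1], present[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        if best >= min_consecutive:
            keep_organs.append(organ)
        else:
            warnings.warn(
                f"organ {organ!r} spans fewer than {min_consecutive} consecutive "
                "age bins and is excluded",
                stacklevel=2,
            )
    out = out[out["organ"].isin(keep_organs)]
    if out.empty:
        raise ValueError("no organs left after age-bin coverage filtering")
    return out


def _design_matrix(
    sample_meta: pd.DataFrame,
    main: pd.Series,
    confounders: list[str],
) -> tuple[np.ndarray, list[str]]:
    """Intercept + main-effect column + dummy-coded confounders.

    Constant (all-equal) confounders are dropped; so is an all-zero FACS
    column, which makes an unsorted dataset identical to omitting the
    covariate.
    """
    cols = [np.ones(len(sample_meta))]
    names = ["intercept"]
    for c in confounders:
        v = sample_meta[c]
        if pd.api.types.is_numeric_dtype(v):
            arr = v.to_numpy(dtype=float)
            if np.allclose(arr, arr[0]):
                continue
            cols.append(arr)
            names.append(c)
        else:
            dummies = pd.get_dummies(v, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(f"{c}[{name}]")
    cols.append(np.asarray(main, dtype=float))
    names.append(str(main.name))
    X = np.column_stack(cols)
    return X, names


def fit_nhood_glm(
    counts: NhoodCounts,
    main: pd.Series,
    confounders: list[str] | None = None,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-neighborhood NB GLM of counts on a main covariate.

    ``main`` is the tested per-sample covariate (ordinal age-bin index or
    organ indicator), aligned to ``counts.sample_meta``.  Returns a frame
    with logFC (the main-covariate coefficient), its p-value, and the
    kept-neighborhood mask; neighborhoods with all-zero counts are
    dropped from testing and reported with NaN results.
    """
    Y = counts.counts.to_numpy(dtype=float)
    meta = counts.sample_meta
    confounders = confounders or []
    X, names = _design_matrix(meta, main, confounders)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design after confounder coding")
    offset = np.log(Y.sum(axis=0) + 1e-8)

    nonzero = Y.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} all-zero neighborhoods", stacklevel=2)
    res = fit_nbglm_many(Y[nonzero], X, offset, prior_df=prior_df)

    out = pd.DataFrame(
        {
            "nhood_id": np.arange(Y.shape[0]),
            "logFC": np.nan,
            "pval": np.nan,
            "converged": False,
        }
    )
    ci = len(names) - 1  # main covariate is the last column
    out.loc[nonzero, "logFC"] = res.coef[:, ci]
    out.loc[nonzero, "pval"] = res.pvalues[:, ci]
    out.loc[nonzero, "converged"] = res.converged
    if counts.labels is not None:
        out["label"] = counts.labels.to_numpy()
    return out


def spatial_fdr(p_values: np.ndarray, kth_nn_distances: np.ndarray) -> np.ndarray:
    """Weighted Benjamini–Hochberg adjustment with density weights.

    Weight ``w_i = 1 / kth_nn_distance_i``; after sorting by p-value the
    adjusted value is ``min over j >= i of p_(j) * sum(w) / cumsum(w)_j``,
    clipped to [0, 1] and returned in input order.  NaN p-values (dropped
    neighborhoods) stay NaN and take no weight.
    """
    p = np.asarray(p_values, dtype=float)
    d = np.asarray(kth_nn_distances, dtype=float)
    if p.shape != d.shape:
        raise ValueError("p-values and distances must have equal length")
    ok = ~np.isnan(p)
    if (d[ok] <= 0).any():
        raise ValueError("kth-NN distance must be positive (weight undefined)")
    out = np.full_like(p, np.nan)
    if ok.sum() == 0:
        return out
    w = 1.0 / d[ok]
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    cumw = np.cumsum(w[order])
    q = ps[order] * w.sum() / cumw
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    res = np.empty_like(q)
    res[order] = q
    out[ok] = res
    return out


def test_age_trend(
    counts: NhoodCounts,
    kth_nn_distances: np.ndarray,
    bin_width: float = 2.0,
    confounders: list[str] | None = None,
    categorical_age: bool = False,
) -> DAResult:
    """Differential abundance across gestational-age bins.

    Samples are binned (organs with <3 consecutive bins excluded) and a
    single ordinal slope per neighborhood is estimated, i.e. the log fold
    change in abundance per age bin.  With ``categorical_age`` the last-
    versus-first bin contrast is used instead.
    """
    meta = bin_gestational_ages(counts.sample_meta, bin_width=bin_width)
    sub = NhoodCounts(
        counts=counts.counts.loc[:, meta.index],
        sample_meta=meta,
        labels=counts.labels,
    )
    if categorical_age:
        main = (meta["age_bin"] == meta["age_bin"].max()).astype(float)
        main.name = "age_bin_top"
    else:
        main = (meta["age_bin"] + 1).astype(float)
        main.name = "age_bin"
    conf = [c for c in (confounders or ["facs_factor"]) if c in meta.columns]
    tab = fit_nhood_glm(sub, main, conf)
    tab["spatial_fdr"] = spatial_fdr(tab["pval"].to_numpy(), np.asarray(kth_nn_distances))
    return DAResult(table=tab)


def test_organ_specificity(
    counts: NhoodCounts,
    kth_nn_distances: np.ndarray,
    target_organ: str,
    confounders: list[str] | None = None,
    fdr_threshold: float = 0.01,
) -> DAResult:
    """Organ-versus-rest differential abundance.

    Neighborhoods with a positive organ coefficient and spatial FDR below
    ``fdr_threshold`` are flagged as organ-enriched.
    """
    meta = counts.sample_meta
    if meta["organ"].nunique() < 2:
        raise ValueError("organ test requires at least two organs")
    n_target = int((meta["organ"] == target_organ).sum())
    if n_target < 2:
        raise ValueError(f"target organ {target_organ!r} has fewer than 2 samples")
    main = (meta["organ"] == target_organ).astype(float)
    main.name = f"organ[{target_organ}]"
    conf = [c for c in (confounders or ["facs_factor"]) if c in meta.columns]
    tab = fit_nhood_glm(counts, main, conf)
    tab["spatial_fdr"] = spatial_fdr(tab["pval"].to_numpy(), np.asarray(kth_nn_distances))
    tab["flagged"] = (tab["logFC"] > 0) & (tab["spatial_fdr"] < fdr_threshold)
    return DAResult(table=tab)
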