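"""Immune-receptor and proliferation statistics.

Group comparisons (e.g., B1 versus mature B cells, unconventional versus
conventional T cells) of cycling fractions, junction/NP-insertion lengths
and somatic mutation loads are run as regressions controlling for donor
and organ as fixed-effect covariates.  Segment-usage biases are tested
per segment with logistic regression (BH-adjusted across segments of a
class) or with Pearson chi-squared tests on used/not-used contingency
tables; per-sample usage-proportion vectors are summarized by PCA with
per-cell-type centroids and 80% Gaussian confidence ellipses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cycling_fraction_test",
    "chain_feature_regression",
    "mutation_frequency",
    "segment_usage_logit",
    "segment_usage_chi2",
    "usage_pca",
]

_GAP_CHARS = set(".-")
# chi-squared(2 df) quantile at 0.80, the scaling of the 80% ellipse
CHI2_80_2DF = float(stats.chi2.ppf(0.80, df=2))


def _covariate_matrix(df: pd.DataFrame, group_col: str, covariates: list[str]):
    cols = [np.ones(len(df))]
    names = ["intercept"]
    g = pd.get_dummies(df[group_col], drop_first=True)
    for c in g.columns:
        cols.append(g[c].to_numpy(dtype=float))
        names.append(f"{group_col}[{c}]")
    group_cols = list(range(1, 1 + g.shape[1]))
    for cov in covariates:
        if df[cov].nunique() < 2:
            continue
        d = pd.get_dummies(df[cov], drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(f"{cov}[{c}]")
    return np.column_stack(cols), names, group_cols


def cycling_fraction_test(
    cells: pd.DataFrame,
    marker_col: str = "MKI67_count",
    group_col: str = "group",
    covariates: tuple[str, ...] = ("donor", "organ"),
    min_cells: int = 10,
) -> dict:
    """Cycling fractions per (group, organ) plus a logistic group test.

    A cell is cycling when its raw marker count is positive.  Per-(group,
    organ) fractions are reported only where at least ``min_cells`` cells
    were profiled; the group effect is a logistic regression of cycling
    on group, donor and organ, returning the odds ratio with Wald p.
    """
    if marker_col not in cells.columns:
        raise ValueError(f"marker column {marker_col!r} absent")
    df = cells.copy()
    df["cycling"] = (df[marker_col] > 0).astype(float)

    tab = (
        df.groupby([group_col, "organ"], observed=True)["cycling"]
        .agg(fraction="mean", n="size")
        .reset_index()
    )
    tab = tab[tab["n"] >= min_cells].reset_index(drop=True)

    X, names, gcols = _covariate_matrix(df, group_col, list(covariates))
    gi = gcols[0]
    y = df["cycling"].to_numpy()
    penalized = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        coef = float(fit.params[gi])
        ci = fit.conf_int()[gi]
        lo, hi, pval = float(ci[0]), float(ci[1]), float(fit.pvalues[gi])
        if not np.isfinite([coef, lo, hi]).all() or abs(coef) > 15:
            raise ValueError("separation")
    except Exception:
        # tiny or separated fixtures: ridge-penalized fit, flagged, no p
        beta = _penalized_logit(y, X)
        coef, lo, hi, pval, penalized = float(beta[gi]), np.nan, np.nan, np.nan, True
    return {
        "fractions": tab,
        "odds_ratio": float(np.exp(coef)),
        "or_ci": (float(np.exp(lo)), float(np.exp(hi))),
        "pval": pval,
        "coef_name": names[gi],
        "penalized": penalized,
    }


def chain_feature_regression(
    chains: pd.DataFrame,
    feature: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("donor", "organ"),
) -> dict:
    """Linear regression of a chain feature on group, donor and organ.

    NP-insertion lengths (np1_length, np2_length) are restricted to
    records flagged as having high-quality D-gene mapping.  Returns the
    group coefficient with 95% CI and p, plus per-group means with 95%
    CIs for plotting.
    """
    allowed = {"np1_length", "np2_length", "junction_length", "mutation_frequency"}
    if feature not in allowed:
        raise ValueError(f"feature must be one of {sorted(allowed)}")
    df = chains.dropna(subset=[feature]).copy()
    if feature in {"np1_length", "np2_length"} and "d_quality" in df.columns:
        df = df[df["d_quality"].astype(bool)]
    for g, sub in df.groupby(group_col, observed=True):
        if sub.empty:
            raise ValueError(f"feature {feature!r} all-missing in group {g!r}")

    X, names, gcols = _covariate_matrix(df, group_col, list(covariates))
    fit = sm.OLS(df[feature].to_numpy(dtype=float), X).fit()
    gi = gcols[0]
    ci = fit.conf_int()[gi]

    means = []
    for g, sub in df.groupby(group_col, observed=True):
        v = sub[feature].to_numpy(dtype=float)
        se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        means.append(
            {
                "group": g,
                "mean": v.mean(),
                "ci_low": v.mean() - 1.96 * se,
                "ci_high": v.mean() + 1.96 * se,
                "n": len(v),
            }
        )
    return {
        "coef": float(fit.params[gi]),
        "ci": (float(ci[0]), float(ci[1])),
        "pval": float(fit.pvalues[gi]),
        "coef_name": names[gi],
        "group_means": pd.DataFrame(means),
    }


def mutation_frequency(observed: str, germline: str) -> float:
    """Fraction of mismatching non-gap positions between aligned sequences.

    Positions where either sequence carries a gap character ('.' or '-')
    or an N are excluded from the comparison.
    """
    if len(observed) != len(germline):
        raise ValueError("aligned sequences must have equal length")
    compared = mismatches = 0
    for a, b in zip(observed.upper(), germline.upper()):
        if a in _GAP_CHARS or b in _GAP_CHARS or a == "N" or b == "N":
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable positions")
    return mismatches / compared


def _penalized_logit(y: np.ndarray, X: np.ndarray, ridge: float = 1.0):
    """Small-ridge IRLS logistic fit, used when ML separation occurs."""
    p = X.shape[1]
    beta = np.zeros(p)
    pen = np.eye(p) * ridge
    pen[0, 0] = 0.0
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T * W @ X + pen
        g = X.T @ (y - mu) - pen @ beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def segment_usage_logit(
    chains: pd.DataFrame,
    segment_class: str = "v_call",
    group_col: str = "group",
    covariates: tuple[str, ...] = ("donor", "organ"),
    min_uses: int = 5,
) -> pd.DataFrame:
    """Per-segment used/not-used logistic regression with BH adjustment.

    Each segment of the class is modeled as usage ~ group + donor +
    organ, reporting the group log odds ratio with its Wald 95% CI;
    segments with fewer than ``min_uses`` total uses are skipped.
    On (quasi-)separation a ridge-penalized fit supplies a finite odds
    ratio, flagged in the ``penalized`` column with p set to NaN.
    """
    segs = chains[segment_class].value_counts()
    segs = segs[segs >= min_uses].index.tolist()
    X, names, gcols = _covariate_matrix(chains, group_col, list(covariates))
    gi = gcols[0]
    rows = []
    for seg in segs:
        y = (chains[segment_class] == seg).to_numpy(dtype=float)
        penalized = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            coef = float(fit.params[gi])
            pval = float(fit.pvalues[gi])
            ci_low, ci_high = (float(v) for v in fit.conf_int()[gi])
            if not fit.mle_retvals.get("converged", True) or abs(coef) > 15:
                raise ValueError("separation")
        except Exception:
            beta = _penalized_logit(y, X)
            coef, pval, penalized = float(beta[gi]), np.nan, True
            ci_low = ci_high = np.nan
        rows.append(
            {
                "segment": seg,
                "log_or": coef,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "odds_ratio": float(np.exp(coef)),
                "pval": pval,
                "penalized": penalized,
            }
        )
    out = pd.DataFrame(rows)
    adj = np.full(len(out), np.nan)
    ok = out["pval"].notna().to_numpy()
    if ok.any():
        adj[ok] = multipletests(out.loc[ok, "pval"], method="fdr_bh")[1]
    out["padj"] = adj
    return out


def segment_usage_chi2(contingency: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-segment Pearson chi-squared of used/not-used across cell types.

    ``contingency`` holds usage counts, segments × cell types; column
    totals give the not-used complement per segment.  No continuity
    correction is applied; p-values are BH-adjusted across segments.
    """
    tab = pd.DataFrame(contingency)
    counts = tab.to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero contingency table")
    totals = counts.sum(axis=0)
    rows = []
    for i, seg in enumerate(tab.index):
        used = counts[i]
        table = np.vstack([used, totals - used])
        if table.sum() == 0 or (table.sum(axis=1) == 0).any():
            rows.append({"segment": seg, "chi2": np.nan, "pval": np.nan})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"segment": seg, "chi2": float(chi2), "pval": float(p)})
    out = pd.DataFrame(rows)
    ok = out["pval"].notna().to_numpy()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok] = multipletests(out.loc[ok, "pval"], method="fdr_bh")[1]
    out["padj"] = adj
    return out


def usage_pca(
    chains: pd.DataFrame,
    sample_key: str = "sample_id",
    celltype_key: str = "celltype",
    segment_cols: tuple[str, ...] = ("v_call", "j_call"),
    min_cells: int = 20,
) -> dict:
    """PCA of per-sample segment-usage proportions with 80% contours.

    Samples with fewer than ``min_cells`` chains are dropped.  Usage
    proportions are computed per segment family (each of ``segment_cols``
    sums to 1 within a sample), centered, and projected onto the first
    two principal components.  Per-cell-type centroids and 80% Gaussian
    confidence ellipses (from the 2-D score covariance, chi-squared(2)
    quantile 3.219) are returned.
    """
    sizes = chains.groupby(sample_key, observed=True).size()
    keep = sizes[sizes >= min_cells].index
    df = chains[chains[sample_key].isin(keep)]
    if keep.size < 3:
        raise ValueError("fewer than 3 samples retained at the cell-count threshold")

    blocks = []
    for col in segment_cols:
        prop = (
            df.groupby([sample_key, col], observed=True)
            .size()
            .unstack(fill_value=0)
            .astype(float)
        )
        prop = prop.div(prop.sum(axis=1), axis=0)
        prop.columns = [f"{col}:{c}" for c in prop.columns]
        blocks.append(prop)
    usage = pd.concat(blocks, axis=1).fillna(0.0)

    pca = PCA(n_components=2, random_state=0)
    scores = pca.fit_transform(usage.to_numpy() - usage.to_numpy().mean(axis=0))
    score_df = pd.DataFrame(scores, index=usage.index, columns=["PC1", "PC2"])
    ct = df.groupby(sample_key, observed=True)[celltype_key].first().loc[usage.index]
    score_df[celltype_key] = ct.to_numpy()

    ellipses = {}
    for c, sub in score_df.groupby(celltype_key, observed=True):
        pts = sub[["PC1", "PC2"]].to_numpy()
        centroid = pts.mean(axis=0)
        if len(pts) > 2:
            cov = np.cov(pts.T)
            vals, vecs = np.linalg.eigh(cov)
            radii = np.sqrt(np.maximum(vals, 0.0) * CHI2_80_2DF)
        else:
            vecs = np.eye(2)
            radii = np.zeros(2)
        ellipses[c] = {"centroid": centroid, "axes": vecs, "radii": radii}
    return {
        "scores": score_df,
        "usage": usage,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "ellipses": ellipses,
    }
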