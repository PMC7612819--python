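"""Differential-abundance model, age binning and weighted spatial FDR."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from devimmune import datest
from devimmune._nbglm import fit_nbglm_many
from devimmune.neighborhoods import NhoodCounts


class TestBinAges:
    def _meta(self, ages, organs):
        return pd.DataFrame({"age_pcw": ages, "organ": organs},
                            index=[f"S{i}" for i in range(len(ages))])

    def test_six_bins_of_width_two(self):
        ages = np.arange(6, 18)  # 6..17
        meta = self._meta(ages, ["TH"] * 12)
        out = datest.bin_gestational_ages(meta, bin_width=2)
        assert sorted(out["age_bin"].unique()) == [0, 1, 2, 3, 4, 5]

    def test_sparse_organ_excluded(self):
        ages = [6, 6, 12, 12, 6, 8, 10, 12]
        organs = ["YS", "YS", "YS", "YS", "TH", "TH", "TH", "TH"]
        with pytest.warns(UserWarning, match="YS"):
            out = datest.bin_gestational_ages(self._meta(ages, organs), bin_width=2)
        assert set(out["organ"]) == {"TH"}

    def test_three_consecutive_bins_retained(self):
        ages = [10, 12, 14]
        out = datest.bin_gestational_ages(self._meta(ages, ["SP"] * 3), bin_width=2)
        assert set(out["organ"]) == {"SP"}

    def test_nonpositive_age_rejected(self):
        with pytest.raises(ValueError):
            datest.bin_gestational_ages(self._meta([0.0, 8.0], ["A", "A"]))


def _simulate_counts(seed, n_nhoods=300, n_samples=12, slope=0.0, planted_frac=1.0):
    """NB counts with a per-bin log-linear relative-abundance trend.

    The trend is planted on the first ``planted_frac`` of neighborhoods and
    sample totals are held flat (columns renormalized), matching the
    compositional nature of neighborhood counts: the model's offset absorbs
    depth, so only relative trends are estimable.  With a small planted
    fraction the renormalization distortion on the planted slope is
    negligible."""
    rng = np.random.default_rng(seed)
    bins = np.repeat(np.arange(6), n_samples // 6)
    size_factor = np.exp(rng.normal(scale=0.2, size=n_samples))
    base = rng.lognormal(2.0, 0.8, size=n_nhoods)
    mu = np.outer(base, size_factor * np.ones(n_samples))
    k = int(round(planted_frac * n_nhoods))
    mu[:k] *= np.exp(slope * bins)
    if planted_frac < 1.0:
        flat_totals = base.sum() * size_factor
        mu *= flat_totals / mu.sum(axis=0)
    lam = rng.gamma(5.0, mu / 5.0)
    counts = rng.poisson(lam)
    meta = pd.DataFrame(
        {
            "age_pcw": 6.0 + 2.0 * bins,
            "organ": "TH",
            "donor_id": [f"D{i}" for i in range(n_samples)],
            "sort_fraction": "unsorted",
        },
        index=[f"S{i}" for i in range(n_samples)],
    )
    return NhoodCounts(counts=pd.DataFrame(counts, columns=meta.index), sample_meta=meta)


class TestNhoodGLM:
    def test_null_pvalues_near_uniform(self):
        """Without a planted effect the p-value distribution passes a KS
        uniformity check in at least 9/10 seeds."""
        from scipy import stats

        ok = 0
        for seed in range(10):
            nc = _simulate_counts(seed, n_nhoods=400)
            main = pd.Series(
                (nc.sample_meta["age_pcw"].to_numpy() - 6) / 2 + 1,
                index=nc.sample_meta.index, name="age_bin",
            )
            tab = datest.fit_nhood_glm(nc, main)
            ks = stats.kstest(tab["pval"].dropna(), "uniform").statistic
            ok += int(ks < 0.08)
        assert ok >= 9

    def test_planted_slope_recovered(self):
        nc = _simulate_counts(42, n_nhoods=1000, slope=np.log(2), planted_frac=0.03)
        main = pd.Series(
            (nc.sample_meta["age_pcw"].to_numpy() - 6) / 2 + 1,
            index=nc.sample_meta.index, name="age_bin",
        )
        tab = datest.fit_nhood_glm(nc, main)
        assert abs(tab["logFC"][:30].median() - np.log(2)) < 0.3

    def test_count_duplication_near_invariant(self):
        """Doubling all counts (with the offset absorbing depth) leaves the
        slope effectively unchanged; exact only in the Poisson limit, so a
        small tolerance is allowed for the NB refit."""
        nc = _simulate_counts(7, n_nhoods=100)
        main = pd.Series(np.tile([1.0, 2, 3, 4, 5, 6], 2)[: len(nc.sample_meta)],
                         index=nc.sample_meta.index, name="age_bin")
        t1 = datest.fit_nhood_glm(nc, main)
        nc2 = NhoodCounts(counts=nc.counts * 2, sample_meta=nc.sample_meta)
        t2 = datest.fit_nhood_glm(nc2, main)
        assert np.nanmedian(np.abs(t1["logFC"] - t2["logFC"])) < 0.01

    def test_contrast_sign_flip_negates_logfc(self):
        nc = _simulate_counts(8, n_nhoods=80)
        main = pd.Series(np.tile(np.arange(6.0) + 1, 2), index=nc.sample_meta.index,
                         name="age_bin")
        t1 = datest.fit_nhood_glm(nc, main)
        t2 = datest.fit_nhood_glm(nc, -main)
        assert np.allclose(t1["logFC"], -t2["logFC"], atol=1e-6)

    def test_agrees_with_statsmodels_at_fixed_dispersion(self):
        """The vectorized IRLS matches statsmodels' NB GLM coefficient-wise
        when run at the same dispersion."""
        nc = _simulate_counts(9, n_nhoods=12)
        Y = nc.counts.to_numpy(dtype=float)
        X = np.column_stack([np.ones(12), np.tile(np.arange(6.0), 2)])
        offset = np.log(Y.sum(axis=0))
        res = fit_nbglm_many(Y, X, offset)
        for i in range(6):
            ref = sm.GLM(
                Y[i], X, family=sm.families.NegativeBinomial(alpha=max(res.alpha[i], 1e-8)),
                offset=offset,
            ).fit()
            assert np.allclose(res.coef[i], ref.params, atol=1e-4)

    def test_all_zero_rows_reported_nan(self):
        nc = _simulate_counts(10, n_nhoods=20)
        nc.counts.iloc[3] = 0
        main = pd.Series(np.tile(np.arange(6.0) + 1, 2), index=nc.sample_meta.index,
                         name="age_bin")
        with pytest.warns(UserWarning, match="all-zero"):
            tab = datest.fit_nhood_glm(nc, main)
        assert np.isnan(tab.loc[3, "logFC"])
        assert tab["logFC"].notna().sum() == 19


class TestSpatialFDR:
    def test_constant_weights_equal_independent_bh(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        got = datest.spatial_fdr(p, np.ones(500))
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(got - ref)) < 1e-12

    def test_textbook_example(self):
        got = datest.spatial_fdr(np.array([0.01, 0.02, 0.03]), np.ones(3))
        assert np.allclose(got, [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_neighborhood(self):
        assert datest.spatial_fdr(np.array([0.2]), np.array([1.5]))[0] == pytest.approx(0.2)

    def test_matches_brute_force_weighted_definition(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = 50
            p = rng.uniform(size=n)
            d = rng.uniform(0.1, 3.0, size=n)
            got = datest.spatial_fdr(p, d)
            w = 1.0 / d
            order = np.argsort(p, kind="stable")
            brute = np.empty(n)
            for rank, j in enumerate(order):
                cands = [
                    p[order[m]] * w.sum() / w[order[: m + 1]].sum()
                    for m in range(rank, n)
                ]
                brute[j] = min(1.0, min(cands))
            assert np.allclose(got, brute, atol=1e-12)

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            datest.spatial_fdr(np.array([0.1]), np.array([0.0]))

    def test_nan_pvalues_passthrough(self):
        p = np.array([0.1, np.nan, 0.5])
        got = datest.spatial_fdr(p, np.ones(3))
        assert np.isnan(got[1]) and not np.isnan(got[0])


class TestOrganSpecificity:
    def _counts_with_organ_effect(self, seed, lfc=0.0):
        rng = np.random.default_rng(seed)
        n_samples = 24
        organs = np.array((["TH"] * 5) + list(rng.choice(["SP", "LI", "BM", "SK"], 19)))
        base = rng.lognormal(3.5, 0.6, size=150)
        sf = np.exp(rng.normal(scale=0.2, size=n_samples))
        mu = np.outer(base, sf)
        mu[:15, organs == "TH"] *= np.exp(lfc)  # first 15 nhoods enriched
        mu *= base.sum() * sf / mu.sum(axis=0)  # flat totals (compositional)
        counts = rng.poisson(rng.gamma(10.0, mu / 10.0))
        meta = pd.DataFrame(
            {"organ": organs, "age_pcw": 12.0, "donor_id": [f"D{i}" for i in range(n_samples)],
             "sort_fraction": "unsorted"},
            index=[f"S{i}" for i in range(n_samples)],
        )
        return NhoodCounts(counts=pd.DataFrame(counts, columns=meta.index), sample_meta=meta)

    def test_planted_enrichment_flagged(self):
        nc = self._counts_with_organ_effect(0, lfc=np.log(3))
        res = datest.test_organ_specificity(nc, np.ones(150), "TH")
        assert res.table["flagged"][:15].mean() >= 0.8

    def test_null_rarely_flagged(self):
        rates = []
        for seed in range(10):
            nc = self._counts_with_organ_effect(seed + 1, lfc=0.0)
            res = datest.test_organ_specificity(nc, np.ones(150), "TH")
            rates.append(res.table["flagged"].mean())
        assert np.mean(rates) <= 0.02

    def test_single_sample_organ_rejected(self):
        nc = self._counts_with_organ_effect(2)
        nc.sample_meta.loc[:, "organ"] = ["XX"] + ["TH"] * 23
        with pytest.raises(ValueError, match="XX"):
            datest.test_organ_specificity(nc, np.ones(150), "XX")


def test_edger_cross_check():
    """The in-package NB-GLM slope agrees with edgeR's QL fit (independent
    implementation) on a shared fixture: logFC correlation > 0.95."""
    nc = _simulate_counts(21, n_nhoods=60, slope=np.log(1.5))
    main = pd.Series(np.tile(np.arange(6.0), 2), index=nc.sample_meta.index, name="bin")
    mine = datest.fit_nhood_glm(nc, main)

    with tempfile.TemporaryDirectory() as td:
        td = Path(td)
        nc.counts.to_csv(td / "counts.csv", index=False)
        main.to_frame().to_csv(td / "design.csv", index=False)
        script = td / "fit.R"
        script.write_text(
            """
            suppressMessages(library(edgeR))
            counts <- as.matrix(read.csv(file.path(commandArgs(TRUE)[1], "counts.csv")))
            bin <- read.csv(file.path(commandArgs(TRUE)[1], "design.csv"))$bin
            d <- DGEList(counts=counts)
            d$samples$norm.factors <- 1
            design <- model.matrix(~bin)
            d <- estimateDisp(d, design)
            fit <- glmQLFit(d, design)
            res <- glmQLFTest(fit, coef=2)
            write.csv(res$table, file.path(commandArgs(TRUE)[1], "out.csv"))
            """
        )
        subprocess.run(["Rscript", str(script), str(td)], check=True, capture_output=True)
        ref = pd.read_csv(td / "out.csv")

    # edgeR reports log2 fold changes; compare on the natural-log scale
    ref_logfc = ref["logFC"].to_numpy() * np.log(2)
    r = np.corrcoef(mine["logFC"], ref_logfc)[0, 1]
    assert r > 0.95
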