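"""Repertoire statistics: cycling fractions, chain-feature regressions,
mutation frequency, segment-usage tests, usage PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devimmune import repertoire, syndata


def _sim_chains(seed=0, **spec_kw):
    cfg = syndata.SimConfig(seed=seed)
    cfg.repertoire = syndata.RepertoireSpec(groups=("matureB", "B1"), **spec_kw)
    cells, chains = syndata.generate_repertoire(cfg)
    chains = chains.merge(cells[["cell_id", "group", "donor", "organ"]], on="cell_id")
    chains["group"] = pd.Categorical(chains["group"], categories=["matureB", "B1"])
    cells["group"] = pd.Categorical(cells["group"], categories=["matureB", "B1"])
    return cells, chains


class TestCyclingFraction:
    def test_simple_fraction(self):
        cells = pd.DataFrame(
            {
                "MKI67_count": [0, 0, 3, 1],
                "group": ["A", "A", "B", "B"],
                "donor": ["D0"] * 4,
                "organ": ["TH"] * 4,
            }
        )
        out = repertoire.cycling_fraction_test(cells, min_cells=1)
        overall = (cells["MKI67_count"] > 0).mean()
        assert overall == 0.5

    def test_small_groups_omitted_from_table(self):
        rng = np.random.default_rng(0)
        n = 200
        cells = pd.DataFrame(
            {
                "MKI67_count": rng.integers(0, 2, n),
                "group": ["A"] * 100 + ["B"] * 100,
                "donor": rng.choice(["D0", "D1"], n),
                "organ": ["TH"] * 191 + ["SP"] * 9,  # 9-cell organ cell
            }
        )
        out = repertoire.cycling_fraction_test(cells, min_cells=10)
        assert not ((out["fractions"]["organ"] == "SP") & (out["fractions"]["n"] < 10)).any()

    def test_planted_cycling_odds_recovered(self):
        cells, _ = _sim_chains(
            seed=5, cells_per_group=2000, cycling_prob={"matureB": 0.10, "B1": 0.25}
        )
        # planted OR = (.25/.75)/(.10/.90) = 3
        out = repertoire.cycling_fraction_test(cells)
        assert 2.0 <= out["odds_ratio"] <= 4.5

    def test_missing_marker_errors(self):
        with pytest.raises(ValueError):
            repertoire.cycling_fraction_test(pd.DataFrame({"group": ["A"]}), marker_col="X")


class TestChainFeatureRegression:
    def test_null_ci_covers_zero(self):
        ok = 0
        for seed in range(10):
            _, chains = _sim_chains(seed=20 + seed, cells_per_group=400)
            out = repertoire.chain_feature_regression(chains, "junction_length")
            ok += int(out["ci"][0] <= 0 <= out["ci"][1])
        assert ok >= 9

    def test_planted_shift_recovered(self):
        _, chains = _sim_chains(
            seed=6, cells_per_group=1000, junction_mean={"matureB": 45.0, "B1": 43.0}
        )
        out = repertoire.chain_feature_regression(chains, "junction_length")
        assert -2.6 <= out["coef"] <= -1.4

    def test_np_features_gated_on_d_quality(self):
        _, chains = _sim_chains(seed=7, cells_per_group=300)
        out = repertoire.chain_feature_regression(chains, "np1_length")
        n_used = out["group_means"]["n"].sum()
        assert n_used == chains["d_quality"].sum()

    def test_reduces_to_two_sample_without_covariates(self):
        """With constant donor and organ the group coefficient equals the
        plain difference of group means."""
        _, chains = _sim_chains(seed=8, cells_per_group=200, n_donors=1, n_organs=1)
        out = repertoire.chain_feature_regression(chains, "junction_length")
        means = chains.groupby("group", observed=True)["junction_length"].mean()
        assert abs(out["coef"] - (means["B1"] - means["matureB"])) < 1e-8

    def test_unknown_feature_rejected(self):
        _, chains = _sim_chains(seed=9, cells_per_group=50)
        with pytest.raises(ValueError):
            repertoire.chain_feature_regression(chains, "v_call")


class TestMutationFrequency:
    def test_identical_sequences(self):
        assert repertoire.mutation_frequency("ACGT", "ACGT") == 0.0

    def test_counting(self):
        germ = "A" * 100
        obs = "C" * 2 + "A" * 98
        assert repertoire.mutation_frequency(obs, germ) == 0.02

    def test_gaps_excluded(self):
        assert repertoire.mutation_frequency("AC.T", "ACGT") == 0.0
        assert repertoire.mutation_frequency("CC-T", "ACGT") == pytest.approx(1 / 3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            L = int(rng.integers(30, 120))
            germ = "".join(rng.choice(list("ACGT"), L))
            seq = list(germ)
            for p in rng.choice(L, size=int(rng.integers(0, L // 3)), replace=False):
                seq[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[p]]
            got = repertoire.mutation_frequency("".join(seq), germ)
            assert got == sum(a != b for a, b in zip(seq, germ)) / L

    def test_errors(self):
        with pytest.raises(ValueError):
            repertoire.mutation_frequency("AC", "ACG")
        with pytest.raises(ValueError):
            repertoire.mutation_frequency("..", "..")

    def test_monotone_in_planted_rate(self):
        rates = [0.0, 0.01, 0.03, 0.06, 0.1]
        means = []
        for r in rates:
            _, chains = _sim_chains(
                seed=10, cells_per_group=200, mutation_rate={"matureB": r, "B1": r}
            )
            means.append(chains["mutation_frequency"].mean())
        rho = stats.spearmanr(rates, means).statistic
        assert rho > 0.95


class TestSegmentUsage:
    def test_planted_or_estimated(self):
        _, chains = _sim_chains(
            seed=11, cells_per_group=2000, usage_odds={("B1", "IGHV1"): 2.0}
        )
        out = repertoire.segment_usage_logit(chains)
        row = out[out["segment"] == "IGHV1"].iloc[0]
        assert 1.4 <= row["odds_ratio"] <= 2.9
        assert row["padj"] < 0.05

    def test_null_adjusted_rate(self):
        hits, total = 0, 0
        for seed in range(5):
            _, chains = _sim_chains(seed=30 + seed, cells_per_group=800)
            out = repertoire.segment_usage_logit(chains)
            hits += (out["padj"] < 0.05).sum()
            total += len(out)
        assert hits / total <= 0.05

    def test_unused_segment_penalized_fallback(self):
        _, chains = _sim_chains(seed=12, cells_per_group=300)
        # force complete separation: segment used only in group B1
        chains = chains.copy()
        mask = chains["group"] == "B1"
        idx = chains.index[mask][:20]
        chains.loc[idx, "v_call"] = "IGHV_SEP"
        out = repertoire.segment_usage_logit(chains)
        row = out[out["segment"] == "IGHV_SEP"].iloc[0]
        assert row["penalized"]
        assert np.isfinite(row["odds_ratio"])


class TestChi2:
    def test_no_association(self):
        tab = pd.DataFrame({"A": [10, 10], "B": [10, 10]}, index=["seg", "other"])
        out = repertoire.segment_usage_chi2(tab)
        assert out["chi2"].iloc[0] == pytest.approx(0.0)
        assert out["pval"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_value(self):
        tab = pd.DataFrame({"A": [30, 10], "B": [10, 30]}, index=["seg", "other"])
        out = repertoire.segment_usage_chi2(tab)
        assert out["chi2"].iloc[0] == pytest.approx(20.0)
        assert out["pval"].iloc[0] == pytest.approx(7.7e-6, rel=0.05)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(1, 60, size=(4, 3))
            tab = pd.DataFrame(counts, index=[f"s{i}" for i in range(4)])
            out = repertoire.segment_usage_chi2(tab)
            totals = counts.sum(axis=0)
            for i in range(4):
                table = np.vstack([counts[i], totals - counts[i]])
                ref = stats.chi2_contingency(table, correction=False)[0]
                assert abs(out["chi2"].iloc[i] - ref) < 1e-8

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            repertoire.segment_usage_chi2(pd.DataFrame({"A": [0], "B": [0]}))


class TestUsagePCA:
    def _chains_with_samples(self, seed=13):
        rng = np.random.default_rng(seed)
        rows = []
        # two cell types with disjoint planted V preferences
        for s in range(12):
            ct = "uncT" if s % 2 else "convT"
            vs = ["TRAV1", "TRAV2"] if ct == "uncT" else ["TRAV7", "TRAV8"]
            n = 25 if s != 0 else 19  # first sample below threshold
            for c in range(n):
                rows.append(
                    {
                        "sample_id": f"S{s}",
                        "celltype": ct,
                        "v_call": rng.choice(vs),
                        "j_call": rng.choice(["TRAJ1", "TRAJ2"]),
                    }
                )
        return pd.DataFrame(rows)

    def test_small_samples_excluded(self):
        out = repertoire.usage_pca(self._chains_with_samples())
        assert "S0" not in out["scores"].index

    def test_proportions_sum_per_family(self):
        out = repertoire.usage_pca(self._chains_with_samples())
        usage = out["usage"]
        v_cols = [c for c in usage.columns if c.startswith("v_call:")]
        j_cols = [c for c in usage.columns if c.startswith("j_call:")]
        assert np.allclose(usage[v_cols].sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(usage[j_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_disjoint_preferences_separate_on_pc1(self):
        out = repertoire.usage_pca(self._chains_with_samples())
        sc = out["scores"]
        g = sc.groupby("celltype", observed=True)["PC1"]
        centroid_sep = abs(g.mean().diff().iloc[-1])
        within_sd = g.std().max()
        assert centroid_sep > 3 * within_sd

    def test_too_few_samples_rejected(self):
        df = self._chains_with_samples()
        df = df[df["sample_id"].isin(["S1", "S2"])]
        with pytest.raises(ValueError):
            repertoire.usage_pca(df)

    def test_ellipse_scaling_constant(self):
        # 80% bivariate normal contour radius^2 = chi2(2df) quantile
        assert repertoire.CHI2_80_2DF == pytest.approx(3.2189, abs=1e-3)
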