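"""KNN graph, neighborhood construction, counting, labeling, FACS factor."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from devimmune import neighborhoods
from conftest import make_cells_from_obs


class TestBuildKNN:
    def test_line_points_match_brute_force(self):
        """5 distinct points on a line, k=2: out-neighbors are the 2 closest,
        verified against all-pairs distances."""
        x = np.array([0.0, 1.0, 2.5, 4.5, 7.0])[:, None]
        g = neighborhoods.build_knn(x, k=2)
        d = np.abs(x - x.T)
        np.fill_diagonal(d, np.inf)
        for i in range(5):
            expected = set(np.argsort(d[i], kind="stable")[:2])
            assert set(g.indices[i]) == expected

    def test_complete_graph_at_k_n_minus_1(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(8, 3))
        g = neighborhoods.build_knn(emb, k=7)
        assert g.adjacency.sum() == 8 * 7

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(40, 4))
        g = neighborhoods.build_knn(emb, k=5)
        perm = rng.permutation(40)
        g2 = neighborhoods.build_knn(emb[perm], k=5)
        A = g.adjacency.toarray()
        A2 = g2.adjacency.toarray()
        # relabel: edge (i,j) in permuted graph equals (perm[i], perm[j])
        back = A2[np.argsort(perm)][:, np.argsort(perm)]
        assert np.array_equal(A, back)

    def test_invalid_k(self):
        emb = np.zeros((5, 2))
        with pytest.raises(ValueError):
            neighborhoods.build_knn(emb, k=0)
        with pytest.raises(ValueError):
            neighborhoods.build_knn(emb, k=5)

    def test_symmetric_no_self_loops(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(30, 3))
        g = neighborhoods.build_knn(emb, k=4)
        A = g.adjacency.toarray()
        assert (A == A.T).all()
        assert not A.diagonal().any()


class TestMakeNeighborhoods:
    def test_sampled_count_formula(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(1000, 4))
        g = neighborhoods.build_knn(emb, k=10)
        nh = neighborhoods.make_neighborhoods(g, emb, prop=0.05, seed=0)
        # ceil(0.05 * 1000) = 50 sampled before refinement/deduplication
        assert len(nh.index_cells) <= 50
        assert len(nh.index_cells) > 0

    def test_contains_index_cell_and_min_size(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(500, 5))
        g = neighborhoods.build_knn(emb, k=20)
        nh = neighborhoods.make_neighborhoods(g, emb, prop=0.1, seed=1)
        memb = nh.membership.toarray()
        for r, i in enumerate(nh.index_cells):
            assert memb[r, i]
            # union symmetrization keeps at least k/2 members on a blob
            assert memb[r].sum() >= 10

    def test_refinement_never_increases_count(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(400, 3))
        g = neighborhoods.build_knn(emb, k=15)
        nh = neighborhoods.make_neighborhoods(g, emb, prop=0.2, seed=2)
        assert len(nh.index_cells) <= int(np.ceil(0.2 * 400))

    def test_bad_prop(self):
        rng = np.random.default_rng(6)
        emb = rng.normal(size=(50, 2))
        g = neighborhoods.build_knn(emb, k=5)
        with pytest.raises(ValueError):
            neighborhoods.make_neighborhoods(g, emb, prop=0.0, seed=0)


class TestCounting:
    def test_direct_enumeration(self, tiny_nhoods):
        obs = pd.DataFrame(
            {
                "sample_id": ["A", "A", "B", "B", "B"],
                "celltype_label": list("xxyyy"),
            },
            index=[f"c{i}" for i in range(5)],
        )
        cells = make_cells_from_obs(obs)
        nc = neighborhoods.count_cells_by_sample(tiny_nhoods, cells)
        # nhood {c0,c1,c2}: A:2, B:1 ; nhood {c2,c3}: A:0, B:2
        assert nc.counts.loc[0, "A"] == 2 and nc.counts.loc[0, "B"] == 1
        assert nc.counts.loc[1, "A"] == 0 and nc.counts.loc[1, "B"] == 2

    def test_conservation_total(self, tiny_nhoods):
        obs = pd.DataFrame(
            {"sample_id": list("AABBB"), "celltype_label": list("xxyyy")},
            index=[f"c{i}" for i in range(5)],
        )
        nc = neighborhoods.count_cells_by_sample(tiny_nhoods, make_cells_from_obs(obs))
        per_cell_memberships = np.asarray(tiny_nhoods.membership.sum(axis=0)).ravel()
        assert nc.counts.to_numpy().sum() == per_cell_memberships.sum()

    def test_random_fixture_vs_double_loop(self):
        rng = np.random.default_rng(7)
        n = 2000
        emb = rng.normal(size=(n, 4))
        g = neighborhoods.build_knn(emb, k=8)
        nh = neighborhoods.make_neighborhoods(g, emb, prop=0.03, seed=3)
        obs = pd.DataFrame(
            {
                "sample_id": rng.choice([f"S{i}" for i in range(6)], size=n),
                "celltype_label": rng.choice(list("abc"), size=n),
            },
            index=[f"c{i}" for i in range(n)],
        )
        nc = neighborhoods.count_cells_by_sample(nh, make_cells_from_obs(obs))
        memb = nh.membership.toarray()
        sample_arr = obs["sample_id"].to_numpy()
        for i in range(memb.shape[0]):
            for s in nc.counts.columns:
                assert nc.counts.loc[i, s] == int(np.sum(memb[i] & (sample_arr == s)))


class TestLabeling:
    def _label(self, member_labels):
        n = len(member_labels)
        memb = sparse.csr_matrix(np.ones((1, n), dtype=bool))
        nh = neighborhoods.NeighborhoodSet(
            index_cells=np.array([0]), membership=memb, kth_nn_distance=np.array([1.0])
        )
        return neighborhoods.label_neighborhoods(nh, np.array(member_labels)).iloc[0]

    def test_clear_majority(self):
        assert self._label(["A"] * 6 + ["B"] * 4) == "A"

    def test_plurality_below_half_is_mixed(self):
        assert self._label(["A"] * 4 + ["B"] * 3 + ["C"] * 3) == "Mixed"

    def test_tie_is_mixed(self):
        assert self._label(["A"] * 5 + ["B"] * 5) == "Mixed"

    def test_exact_half_unique_mode_labeled(self):
        # modal share exactly 50% with a unique mode is not "less than 50%"
        assert self._label(["A"] * 5 + ["B"] * 3 + ["C"] * 2) == "A"

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        labels = rng.choice(list("abcd"), size=200)
        memb = sparse.csr_matrix(rng.random((20, 200)) < 0.2)
        memb[:, 0] = True  # avoid empty rows
        nh = neighborhoods.NeighborhoodSet(
            index_cells=np.arange(20), membership=memb.tocsr(),
            kth_nn_distance=np.ones(20),
        )
        out = neighborhoods.label_neighborhoods(nh, labels)
        perm = rng.permutation(200)
        nh2 = neighborhoods.NeighborhoodSet(
            index_cells=np.arange(20),
            membership=sparse.csr_matrix(memb.toarray()[:, perm]),
            kth_nn_distance=np.ones(20),
        )
        out2 = neighborhoods.label_neighborhoods(nh2, labels[perm])
        assert (out == out2).all()


class TestFacsFactor:
    def _meta(self, fracs):
        return pd.DataFrame(
            {"sort_fraction": fracs}, index=[f"S{i}" for i in range(len(fracs))]
        )

    def test_unsorted_zero(self):
        out = neighborhoods.facs_correction_factor(self._meta(["unsorted"]))
        assert out.iloc[0] == 0.0

    def test_measured_fraction_log(self):
        out = neighborhoods.facs_correction_factor(
            self._meta(["CD45pos"]), {"S0": 0.4}
        )
        assert np.isclose(out.iloc[0], np.log(0.4))

    def test_two_fractions_sum_to_one(self):
        out = neighborhoods.facs_correction_factor(
            self._meta(["CD45pos", "CD45neg"]), {"S0": 0.3, "S1": 0.7}
        )
        assert np.isclose(out.iloc[0], np.log(0.3))
        assert np.isclose(out.iloc[1], np.log(0.7))

    def test_missing_proportion_errors(self):
        with pytest.raises(ValueError, match="S0"):
            neighborhoods.facs_correction_factor(self._meta(["CD45pos"]), {})
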