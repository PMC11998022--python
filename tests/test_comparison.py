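"""Pseudotime binning, bin distances and mapping, layout, clustering,
differential expression, signature scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from statemap import BinDistance, DiffusionSpace, NormalizedMatrix
from statemap import comparison as cp


def flat_space(coords):
    """DiffusionSpace whose multiscale coordinates are given directly."""
    coords = np.atleast_2d(np.asarray(coords, float))
    if coords.shape[0] < coords.shape[1]:
        coords = coords.T
    lam = np.array([1.0] + [0.5] * coords.shape[1])
    psi = np.column_stack([np.ones(len(coords)), coords])
    return DiffusionSpace(lam, psi, coords.shape[1], coords)


class TestBins:
    def test_two_cells_two_bins(self):
        bp = cp.pseudotime_bins(np.array([0.01, 0.99]), n_bins=2)
        assert bp.bin_ids.tolist() == [0, 1]

    def test_boundaries_match_histogram_edges(self):
        rng = np.random.default_rng(0)
        pt = rng.uniform(0, 1, 500)
        bp = cp.pseudotime_bins(pt, n_bins=10)
        expect, _ = np.histogram(pt, bins=np.linspace(0, 1, 11))
        got = bp.bin_meta.sort_values("pt_lo")["n_cells"].to_numpy()
        assert got.tolist() == expect.tolist()

    def test_pt_one_lands_in_last_bin(self):
        bp = cp.pseudotime_bins(np.array([0.0, 1.0]), n_bins=4)
        assert bp.bin_meta["pt_hi"].max() == 1.0

    def test_stratification_never_mixes_labels(self):
        rng = np.random.default_rng(1)
        pt = rng.uniform(0, 1, 200)
        lab = rng.choice(["a", "b"], 200)
        bp = cp.pseudotime_bins(pt, n_bins=5, stratify_by=lab)
        for b in range(len(bp.bin_meta)):
            assert len(set(lab[bp.bin_ids == b])) == 1

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            cp.pseudotime_bins(np.array([0.5]), n_bins=1)


class TestBinDistance:
    def test_singleton_bin_against_itself_is_zero(self):
        ds = flat_space(np.array([[0.0], [5.0]]))
        bp = cp.pseudotime_bins(np.array([0.0, 1.0]), n_bins=2)
        bd = cp.bin_distance_matrix(ds, bp, bp)
        assert bd.matrix[0, 0] == 0.0
        assert bd.matrix[1, 1] == 0.0

    def test_one_dimensional_brute_force(self):
        # bins A={0,1}, B={2} in 1-D coordinates -> mean distance 1.5
        ds = flat_space(np.array([[0.0], [1.0], [2.0]]))
        pa = cp.pseudotime_bins(np.array([0.1, 0.1, 0.9]), n_bins=2)
        bd = cp.bin_distance_matrix(ds, pa, pa)
        assert bd.matrix[0, 1] == pytest.approx(1.5)

    def test_identical_trajectory_minimum_on_diagonal(self):
        rng = np.random.default_rng(2)
        pt = rng.uniform(0, 1, 400)
        coords = np.column_stack([pt * 10, rng.normal(0, 0.1, 400)])
        ds = flat_space(coords)
        bp = cp.pseudotime_bins(pt, n_bins=10)
        bd = cp.bin_distance_matrix(ds, bp, bp)
        M = bd.matrix
        frac = np.mean([np.argmin(M[i]) == i for i in range(M.shape[0])])
        assert frac >= 0.95


class TestMapBins:
    def _bd(self, M):
        n, m = M.shape
        rows = pd.DataFrame({"bin": range(n), "pt_lo": 0.0, "pt_hi": 1.0,
                             "label": "", "n_cells": 1})
        cols = pd.DataFrame({"bin": range(m), "pt_lo": 0.0, "pt_hi": 1.0,
                             "label": [f"L{j}" for j in range(m)], "n_cells": 1})
        return BinDistance(M.astype(float), rows, cols)

    def test_identity_for_identical_partitions(self):
        M = np.abs(np.subtract.outer(np.arange(4), np.arange(4)))
        out = cp.map_bins(self._bd(M))
        assert out["mapped_bin_b"].tolist() == [0, 1, 2, 3]

    def test_ties_break_to_lower_index(self):
        M = np.array([[1.0, 1.0, 2.0]])
        out = cp.map_bins(self._bd(M))
        assert out["mapped_bin_b"].tolist() == [0]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        M = rng.random((6, 5))
        a = cp.map_bins(self._bd(M))
        perm = rng.permutation(6)
        b = cp.map_bins(self._bd(M[perm]))
        assert a["mapped_bin_b"].to_numpy()[perm].tolist() == \
            b["mapped_bin_b"].tolist()


class TestLayout:
    def _two_cliques(self):
        import scipy.sparse as sp
        W = np.zeros((8, 8))
        W[:4, :4] = 1.0
        W[4:, 4:] = 1.0
        np.fill_diagonal(W, 0)
        W[0, 4] = W[4, 0] = 0.01
        return sp.csr_matrix(W)

    def test_same_seed_same_coordinates(self):
        A = self._two_cliques()
        a = cp.coembed_layout(A, iterations=30, seed=1)
        b = cp.coembed_layout(A, iterations=30, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_cliques_separate(self):
        A = self._two_cliques()
        xy = cp.coembed_layout(A, iterations=60, seed=0)
        c1, c2 = xy[:4].mean(axis=0), xy[4:].mean(axis=0)
        within = np.linalg.norm(xy[:4] - c1, axis=1).mean()
        assert np.linalg.norm(c1 - c2) > 2 * within

    def test_stress_decreases_with_iterations(self):
        A = self._two_cliques()
        s_few = cp.layout_stress(cp.coembed_layout(A, iterations=2, seed=0), A)
        s_many = cp.layout_stress(cp.coembed_layout(A, iterations=80, seed=0), A)
        assert s_many <= s_few


class TestClusterCells:
    def _blobs(self, n_blobs, seed, n_per=40, sep=12.0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.normal(sep * i, 1.0, size=(n_per, 3))
                            for i in range(n_blobs)])
        truth = np.repeat(np.arange(n_blobs), n_per)
        return X, truth

    @pytest.mark.parametrize("method", ["community", "kmeans_diffusion"])
    def test_two_blobs_exact(self, method):
        X, truth = self._blobs(2, seed=0)
        labels = cp.cluster_cells(X, method=method, k=30, n_clusters=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_planted_five_partition_recovered(self):
        aris = []
        for seed in range(10):
            X, truth = self._blobs(5, seed=seed)
            labels = cp.cluster_cells(X, method="community", k=15, seed=0)
            aris.append(adjusted_rand_score(truth, labels))
        assert np.mean(aris) >= 0.9

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            cp.cluster_cells(np.zeros((4, 2)), method="mystery")


class TestDifferentialGenes:
    def _nm(self, X):
        return NormalizedMatrix(np.asarray(X, float), 1.0, 0.1)

    def test_identical_groups_find_nothing(self):
        rng = np.random.default_rng(4)
        X = np.tile(rng.normal(size=(1, 20)), (30, 1)) + rng.normal(
            0, 0.01, size=(30, 20))
        labels = np.array([0] * 15 + [1] * 15)
        out = cp.differential_genes(self._nm(X), labels, 0, p_max=0.01,
                                    lfc_min=0.5)
        assert len(out) == 0

    def test_ranksum_p_matches_exact_permutation_oracle(self):
        a = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        b = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        got = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="exact").pvalue
        # enumerate all 10-choose-5 group assignments
        pool = np.concatenate([a, b])
        u_obs = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        count = 0
        total = 0
        for idx in itertools.combinations(range(10), 5):
            mask = np.zeros(10, bool)
            mask[list(idx)] = True
            u = stats.mannwhitneyu(pool[mask], pool[~mask]).statistic
            stat = min(u, 25 - u)
            obs = min(u_obs, 25 - u_obs)
            count += stat <= obs
            total += 1
        assert got == pytest.approx(count / total, abs=1e-12)

    def test_planted_marker_ranked_first_and_top_n(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 30))
        labels = np.array([0] * 30 + [1] * 30)
        X[labels == 0, 7] += 5.0
        out = cp.differential_genes(self._nm(X), labels, 0, p_max=0.05,
                                    lfc_min=1.0, top_n=50)
        assert out.iloc[0]["gene"] == "g7"
        assert len(out) <= 50

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            cp.differential_genes(self._nm(np.zeros((3, 2))),
                                  np.array([0, 1, 1]), 0)


class TestSignatureScores:
    def test_singleton_set_is_gene_zscore(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 5))
        nm = NormalizedMatrix(X, 1.0, 0.1,
                              np.array([f"g{i}" for i in range(5)], dtype=object))
        out = cp.signature_scores(nm, {"s": ["g2"]})
        z = (X[:, 2] - X[:, 2].mean()) / X[:, 2].std()
        np.testing.assert_allclose(out["s"], z, rtol=1e-9)

    def test_toy_matrix_hand_computation(self):
        X = np.array([[1.0, 0.0, 2.0, 1.0],
                      [3.0, 2.0, 0.0, 1.0],
                      [5.0, 4.0, 4.0, 1.0]])
        nm = NormalizedMatrix(X, 1.0, 0.1,
                              np.array(list("abcd"), dtype=object))
        out = cp.signature_scores(nm, {"s": ["a", "b"]})
        za = (X[:, 0] - 3) / np.std(X[:, 0])
        zb = (X[:, 1] - 2) / np.std(X[:, 1])
        np.testing.assert_allclose(out["s"], (za + zb) / 2, rtol=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(25, 6))
        names = np.array([f"g{i}" for i in range(6)], dtype=object)
        Y = X.copy()
        Y[:, 1] = 100 * Y[:, 1] - 7          # affine change of one gene
        a = cp.signature_scores(NormalizedMatrix(X, 1, 0.1, names),
                                {"s": ["g0", "g1", "g4"]})
        b = cp.signature_scores(NormalizedMatrix(Y, 1, 0.1, names),
                                {"s": ["g4", "g1", "g0"]})   # order shuffled too
        np.testing.assert_allclose(a["s"], b["s"], rtol=1e-9)

    def test_missing_set_named_in_error(self):
        nm = NormalizedMatrix(np.zeros((3, 2)), 1, 0.1,
                              np.array(["x", "y"], dtype=object))
        with pytest.raises(ValueError, match="ghost"):
            cp.signature_scores(nm, {"ghost": ["nope"]})
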