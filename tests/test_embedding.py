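import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst

from ncmce import (
    DistanceMatrix,
    MCKernel,
    SpanningTree,
    embed_pipeline,
    mc_kernel,
    mce_embed,
    minimum_spanning_tree,
    ncmce_embed,
    pairwise_distances,
    pca_embed,
)
from ncmce.errors import DimensionError, DomainError


class TestPairwiseDistances:
    def test_euclidean_345_triangle(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_correlation_identical_rows(self):
        d = pairwise_distances(
            np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]), norm="correlation"
        )
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_anticorrelated_rows(self):
        d = pairwise_distances(
            np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]), norm="correlation"
        )
        assert d.values[0, 1] == pytest.approx(2.0)

    def test_correlation_constant_row_names_sample(self):
        with pytest.raises(DomainError, match="flat"):
            pairwise_distances(
                np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]),
                norm="correlation",
                ids=["flat", "ok"],
            )

    def test_symmetric_zero_diagonal(self, rng):
        d = pairwise_distances(rng.random((6, 4)))
        np.testing.assert_allclose(d.values, d.values.T)
        np.testing.assert_allclose(np.diag(d.values), 0.0)


def brute_force_mst_weight(w: np.ndarray) -> float:
    """Minimum total weight over all spanning trees (edge-subset enumeration)."""
    n = w.shape[0]
    all_edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(all_edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w[i, j] for i, j in subset))
    return best


class TestMinimumSpanningTree:
    def test_three_node_unique_mst(self):
        w = np.array([[0, 1, 4], [1, 0, 2], [4, 2, 0]], dtype=float)
        t = minimum_spanning_tree(DistanceMatrix(w, list("abc")))
        assert [(i, j) for i, j, _ in t.edges] == [(0, 1), (1, 2)]
        assert t.total_weight() == pytest.approx(3.0)

    def test_tie_resolved_to_lexicographically_smaller_pair(self):
        # a=(0,0), b=(1,0), c=(0,1), e=(5,5): e-b and e-c tie at sqrt(41)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        d = pairwise_distances(pts)
        t = minimum_spanning_tree(d)
        assert [(i, j) for i, j, _ in t.edges] == [(0, 1), (0, 2), (1, 3)]
        assert t.total_weight() == pytest.approx(2 + np.sqrt(41))
        assert brute_force_mst_weight(d.values) == pytest.approx(2 + np.sqrt(41))

    def test_two_nodes_single_edge(self):
        t = minimum_spanning_tree(
            DistanceMatrix(np.array([[0.0, 7.0], [7.0, 0.0]]), ["a", "b"])
        )
        assert t.edges == [(0, 1, 7.0)]

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_optimal_weight_matches_brute_force(self, rng, n):
        for _ in range(10):
            pts = rng.random((n, 3))
            d = pairwise_distances(pts)
            t = minimum_spanning_tree(d)
            assert t.total_weight() == pytest.approx(brute_force_mst_weight(d.values))

    def test_integer_weights_with_many_ties_still_optimal(self, rng):
        """Tie-heavy instances: optimality vs scipy, determinism across runs."""
        for _ in range(10):
            n = 7
            w = rng.integers(1, 4, size=(n, n)).astype(float)
            w = np.triu(w, 1)
            w = w + w.T
            d = DistanceMatrix(w, [str(i) for i in range(n)])
            t1 = minimum_spanning_tree(d)
            t2 = minimum_spanning_tree(d)
            assert t1.edges == t2.edges
            assert t1.total_weight() == pytest.approx(scipy_mst(w).sum())


class TestMCKernel:
    def test_path_graph_sums(self):
        t = SpanningTree([(0, 1, 1.0), (1, 2, 2.0)], 3)
        k = mc_kernel(t)
        assert k.values[0, 2] == pytest.approx(3.0)
        np.testing.assert_allclose(np.diag(k.values), 0.0)

    def test_four_point_example_path_sum(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [5.0, 5.0]])
        t = minimum_spanning_tree(pairwise_distances(pts))
        k = mc_kernel(t)
        # path c-a-b-e = 1 + 1 + sqrt(41)
        assert k.values[2, 3] == pytest.approx(2 + np.sqrt(41))

    def test_tree_metric_dominates_euclidean_input(self, rng):
        pts = rng.random((10, 3))
        d = pairwise_distances(pts)
        k = mc_kernel(minimum_spanning_tree(d))
        assert np.all(k.values >= d.values - 1e-9)

    def test_four_point_condition_on_random_instances(self, rng):
        """Additive tree metric: of the three quartet sums, the largest two
        coincide, for every quartet of 100 random instances."""
        for _ in range(100):
            pts = rng.random((6, 3))
            k = mc_kernel(minimum_spanning_tree(pairwise_distances(pts))).values
            for i, j, l, m in itertools.combinations(range(6), 4):
                sums = sorted(
                    [
                        k[i, j] + k[l, m],
                        k[i, l] + k[j, m],
                        k[i, m] + k[j, l],
                    ]
                )
                assert sums[2] - sums[1] == pytest.approx(0.0, abs=1e-9)


class TestNcmceEmbed:
    def test_exchange_kernel_closed_form(self):
        k = MCKernel(np.array([[0.0, 2.0], [2.0, 0.0]]), ["a", "b"])
        e = ncmce_embed(k, 2)
        np.testing.assert_allclose(e.spectrum, [2.0, 2.0])
        # sqrt(S) * V with V = [1,1]/sqrt2 and [1,-1]/sqrt2: |coords| = 1
        np.testing.assert_allclose(np.abs(e.coords), 1.0)
        assert e.coords[0, 0] * e.coords[1, 0] > 0  # dim 1: equal signs
        assert e.coords[0, 1] * e.coords[1, 1] < 0  # dim 2: opposite signs

    def test_rank_one_kernel_has_zero_second_spectrum(self):
        v = np.array([1.0, 2.0, 3.0])
        k = MCKernel(np.outer(v, v), ["a", "b", "c"])
        e = ncmce_embed(k, 2)
        assert e.spectrum[1] == pytest.approx(0.0, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        w = rng.random((6, 6))
        k = (w + w.T) / 2
        np.fill_diagonal(k, 0.0)
        perm = rng.permutation(6)
        e1 = ncmce_embed(MCKernel(k, [str(i) for i in range(6)]), 3)
        e2 = ncmce_embed(MCKernel(k[np.ix_(perm, perm)],
                                  [str(i) for i in perm]), 3)
        np.testing.assert_allclose(e2.coords, e1.coords[perm], atol=1e-8)

    def test_spectrum_non_increasing_and_dimension_error(self, rng):
        w = rng.random((8, 8))
        k = (w + w.T) / 2
        np.fill_diagonal(k, 0.0)
        e = ncmce_embed(MCKernel(k, [str(i) for i in range(8)]), 5)
        assert np.all(np.diff(e.spectrum) <= 1e-12)
        with pytest.raises(DimensionError):
            ncmce_embed(MCKernel(k, [str(i) for i in range(8)]), 9)

    def test_low_rank_reconstruction_is_optimal(self, rng):
        """Rank-d truncation from the embedding factors achieves the SVD
        optimum of the Frobenius approximation error."""
        w = rng.random((7, 7))
        k = (w + w.T) / 2
        np.fill_diagonal(k, 0.0)
        d = 3
        lam, vec = np.linalg.eigh(k)
        order = np.argsort(np.abs(lam))[::-1][:d]
        recon = (vec[:, order] * lam[order]) @ vec[:, order].T
        s_all = np.sort(np.abs(np.linalg.eigvalsh(k)))[::-1]
        optimal = np.sqrt(np.sum(s_all[d:] ** 2))
        assert np.linalg.norm(k - recon) == pytest.approx(optimal, abs=1e-9)
        e = ncmce_embed(MCKernel(k, [str(i) for i in range(7)]), d)
        np.testing.assert_allclose(np.sort(e.spectrum)[::-1], s_all[:d], atol=1e-9)


class TestMceEmbed:
    def test_constant_kernel_centred_away(self):
        k = np.full((5, 5), 3.0)
        np.fill_diagonal(k, 0.0)
        e = mce_embed(MCKernel(k, [str(i) for i in range(5)]), 2)
        assert abs(e.coords[:, 0].sum()) == pytest.approx(0.0, abs=1e-9)

    def test_centering_identity_column_sums_vanish(self, rng):
        w = rng.random((6, 6))
        k = (w + w.T) / 2
        np.fill_diagonal(k, 0.0)
        n = 6
        j = np.eye(n) - np.ones((n, n)) / n
        centred = j @ k @ j
        np.testing.assert_allclose(centred.sum(axis=0), 0.0, atol=1e-9)

    def test_matches_stepwise_svd_oracle(self, rng):
        """Independent route: explicit J K J then a full numpy SVD."""
        w = rng.random((5, 5))
        k = (w + w.T) / 2
        np.fill_diagonal(k, 0.0)
        n = 5
        j = np.eye(n) - np.ones((n, n)) / n
        centred = j @ k @ j
        _, s, vt = np.linalg.svd(centred)
        d = 3
        oracle = vt[:d].T * np.sqrt(s[:d])
        e = mce_embed(MCKernel(k, [str(i) for i in range(5)]), d)
        np.testing.assert_allclose(e.spectrum, s[:d], atol=1e-9)
        np.testing.assert_allclose(np.abs(e.coords), np.abs(oracle), atol=1e-8)


class TestPcaEmbed:
    def test_two_point_full_variance_on_pc1(self):
        e = pca_embed(np.array([[1.0, 0.0], [-1.0, 0.0]]), 1)
        np.testing.assert_allclose(np.sort(e.coords[:, 0]), [-1.0, 1.0])
        assert e.spectrum[0] == pytest.approx(2.0)  # ddof=1 variance

    def test_spectrum_sums_to_total_variance(self, rng):
        x = rng.random((8, 5))
        e = pca_embed(x, 5)
        assert e.spectrum.sum() == pytest.approx(x.var(axis=0, ddof=1).sum())

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        x = rng.random((6, 4))
        centred = x - x.mean(axis=0)
        lam, vec = np.linalg.eigh(centred.T @ centred / (x.shape[0] - 1))
        order = np.argsort(lam)[::-1]
        oracle_scores = centred @ vec[:, order]
        e = pca_embed(x, 4)
        np.testing.assert_allclose(np.abs(e.coords), np.abs(oracle_scores), atol=1e-8)
        np.testing.assert_allclose(e.spectrum, lam[order], atol=1e-10)

    def test_invariant_to_column_shift(self, rng):
        x = rng.random((6, 4))
        shifted = x + np.array([5.0, -2.0, 0.0, 100.0])
        np.testing.assert_allclose(
            pca_embed(x, 2).coords, pca_embed(shifted, 2).coords, atol=1e-8
        )

    def test_dimension_error(self, rng):
        with pytest.raises(DimensionError):
            pca_embed(rng.random((4, 3)), 4)


class TestEmbedPipeline:
    def test_two_sample_end_to_end(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        e = embed_pipeline(x, method="ncMCE", d=2)
        assert e.coords.shape == (2, 2)
        assert e.coords[0, 1] * e.coords[1, 1] < 0  # dim 2 splits the pair

    def test_pca_ignores_norm_with_notice(self, caplog):
        x = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0]])
        with caplog.at_level("INFO"):
            e = embed_pipeline(x, method="PCA", norm="correlation", d=2)
        assert e.method == "PCA"
        assert "ignored" in caplog.text

    def test_methods_share_ids(self, labelled_genotypes):
        for method in ("ncMCE", "MCE", "PCA"):
            e = embed_pipeline(labelled_genotypes, method=method, d=2)
            assert e.ids == labelled_genotypes.sample_ids
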