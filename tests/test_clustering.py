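import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from spnkit.clustering import (
    ch_index,
    cut,
    mss_index,
    pearson_similarity,
    select_clustering,
    similarity_to_distance,
    upgma,
)
from spnkit.synthetic import planted_cluster_invariants


class TestPearson:
    def test_identical_vectors_have_unit_similarity(self):
        X = np.array([[1, 2, 3], [1, 2, 3]])
        R = pearson_similarity(X)
        assert R[0, 1] == pytest.approx(1.0)
        assert similarity_to_distance(R)[0, 1] == pytest.approx(0.0)

    def test_perfect_anticorrelation(self):
        R = pearson_similarity(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 5, size=(6, 8)).astype(float)
        R = pearson_similarity(X)
        for i in range(6):
            for j in range(6):
                x, y = X[i] - X[i].mean(), X[j] - X[j].mean()
                denom = np.sqrt((x**2).sum() * (y**2).sum())
                expected = (x * y).sum() / denom if denom else 0.0
                assert R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_vector_maps_to_zero(self):
        X = np.array([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        R = pearson_similarity(X)
        assert R[0, 1] == 0.0 and R[0, 0] == 1.0

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        R = pearson_similarity(X)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)


class TestUpgma:
    def test_two_leaves(self):
        D = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = upgma(D)
        assert tree.merges == ((0, 1, 0.7, 2),)

    def test_three_point_hand_computed(self):
        """d(0,1)=1, d(0,2)=4, d(1,2)=5: merge {0,1} at 1, then at (4+5)/2."""
        D = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        tree = upgma(D)
        (a, b, h1, _), (c, d, h2, _) = tree.merges
        assert {a, b} == {0, 1} and h1 == pytest.approx(1.0)
        assert h2 == pytest.approx(4.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_merge_heights_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        tree = upgma(D)
        heights = [m[2] for m in tree.merges]
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(42)
        n = 12
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        ours = upgma(D).linkage()
        theirs = linkage(squareform(D, checks=False), method="average")
        assert np.allclose(sorted(ours[:, 2]), sorted(theirs[:, 2]))

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_newick_roundtrippable_by_dendropy(self):
        import dendropy

        D = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        nwk = upgma(D).newick(labels=["a", "b", "c"])
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}


class TestCut:
    def setup_method(self):
        rng = np.random.default_rng(1)
        D = rng.random((7, 7))
        self.D = (D + D.T) / 2
        np.fill_diagonal(self.D, 0)
        self.tree = upgma(self.D)

    def test_k1_single_cluster(self):
        cl = cut(self.tree, 1)
        assert cl.sizes() == (7,)

    def test_k_equals_n_all_singletons(self):
        cl = cut(self.tree, 7)
        assert cl.sizes() == (1,) * 7

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_exactly_k_nonempty_clusters(self, k):
        cl = cut(self.tree, k)
        assert cl.k == k and len(cl.sizes()) == k and all(s > 0 for s in cl.sizes())

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            cut(self.tree, 0)
        with pytest.raises(ValueError):
            cut(self.tree, 8)


class TestIndices:
    def _blobs(self, centers, n=10, scale=0.05, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([c + scale * rng.normal(size=(n, len(c))) for c in centers])
        return X

    def test_ch_peaks_at_true_k(self):
        X = self._blobs([(0, 0), (5, 5)])
        D = similarity_to_distance(pearson_similarity(X))
        tree = upgma(np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)))
        ch2 = ch_index(X, cut(tree, 2))
        assert all(ch2 > ch_index(X, cut(tree, k)) for k in (3, 4, 5))

    def test_ch_matches_sklearn(self):
        from sklearn.metrics import calinski_harabasz_score

        X = self._blobs([(0, 0), (3, 1), (1, 4)], n=8, scale=0.3)
        tree = upgma(np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)))
        cl = cut(tree, 3)
        assert ch_index(X, cl) == pytest.approx(
            calinski_harabasz_score(X, np.array(cl.assignment)), rel=1e-9
        )

    def test_ch_degenerate_returns_inf(self):
        X = np.array([[0.0, 0.0]] * 3 + [[1.0, 1.0]] * 3)
        tree = upgma(np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)))
        assert ch_index(X, cut(tree, 2)) == np.inf

    def test_ch_rejects_extreme_k(self):
        X = self._blobs([(0, 0), (5, 5)], n=3)
        tree = upgma(np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)))
        with pytest.raises(ValueError):
            ch_index(X, cut(tree, 1))

    def test_mss_lower_for_tight_clusters(self):
        X = self._blobs([(0, 0), (5, 5)])
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        tree = upgma(D)
        good = mss_index(D, cut(tree, 2))
        merged = mss_index(D, cut(tree, 1))
        assert good < merged


class TestSelect:
    def test_planted_three_clusters_recovered(self):
        X, labels = planted_cluster_invariants(3, 6, 18, separation=8.0, seed=2)
        table, best = select_clustering(X, range(2, 7))
        assert best.k == 3
        # recovered partition equals the planted one (up to relabelling)
        groups = {}
        for i, c in enumerate(best.assignment):
            groups.setdefault(c, set()).add(labels[i])
        assert all(len(v) == 1 for v in groups.values())

    def test_single_k_range(self):
        X, _ = planted_cluster_invariants(2, 4, 10, separation=6.0, seed=0)
        table, best = select_clustering(X, [2])
        assert list(table["k"]) == [2] and best.k == 2

    def test_empty_range_rejected(self):
        X, _ = planted_cluster_invariants(2, 4, 10, separation=6.0, seed=0)
        with pytest.raises(ValueError):
            select_clustering(X, [])
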