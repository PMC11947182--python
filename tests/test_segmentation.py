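"""SNN graph construction, community detection and region assignment."""

import numpy as np
import pytest
from scipy import sparse
from sklearn.metrics import adjusted_rand_score

from msiregion import (
    assign_regions,
    build_snn_graph,
    cluster_pixels,
    preprocess_for_clustering,
    top_cluster_lipids,
)


class TestPreprocess:
    def test_zero_variance_feature_dropped_with_warning(self, matrix_factory, rng):
        values = rng.uniform(1, 5, (30, 3))
        values[:, 1] = 2.0
        with pytest.warns(UserWarning, match="zero-variance"):
            emb = preprocess_for_clustering(matrix_factory(values), pca_dims=2)
        # two informative features remain -> at most one component
        assert emb.shape == (30, 1)

    def test_standardized_moments(self, matrix_factory, rng):
        """After log1p + z-scoring each retained column has mean 0, var 1."""
        from msiregion.segment import PCA  # noqa: F401 - same pathway

        values = rng.lognormal(3, 1, (200, 4))
        X = np.log1p(values)
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.var(axis=0), 1, rtol=1e-12)
        # and the package's embedding is the PCA of that standardized matrix
        emb = preprocess_for_clustering(matrix_factory(values), pca_dims=3)
        assert emb.shape == (200, 3)
        np.testing.assert_allclose(emb.mean(axis=0), 0, atol=1e-10)

    def test_too_few_informative_features_rejected(self, matrix_factory):
        values = np.ones((10, 2))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                preprocess_for_clustering(matrix_factory(values))


class TestSnnGraph:
    def test_equilateral_configuration_symmetric(self):
        """Equidistant points whose neighbour sets coincide give a complete
        graph with equal weights."""
        pts = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0.5, 100.0]])
        adj = build_snn_graph(pts, k=3, prune=0.0)
        dense = adj.toarray()[:3, :3]
        assert np.allclose(dense, dense.T)
        off = dense[np.triu_indices(3, 1)]
        assert np.all(off > 0) and np.allclose(off, off[0])

    def test_two_separated_triads_disconnect(self):
        """Brute-force neighbour sets: no cross-triad edges survive pruning."""
        a = np.array([[0, 0], [0.1, 0], [0, 0.1]])
        b = a + 100.0
        pts = np.vstack([a, b])
        adj = build_snn_graph(pts, k=2, prune=1 / 15)
        dense = adj.toarray()
        assert np.all(dense[:3, 3:] == 0)
        # oracle: k=2 neighbour sets stay within each triad, so every
        # cross-pair Jaccard is exactly 0
        for i in range(3):
            for j in range(3, 6):
                assert dense[i, j] == 0

    def test_prune_above_one_empties_graph(self):
        pts = np.random.default_rng(0).normal(size=(20, 2))
        adj = build_snn_graph(pts, k=3, prune=1.01)
        assert adj.nnz == 0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            build_snn_graph(np.zeros((5, 2)), k=0)


class TestClusterPixels:
    def _blob_embedding(self, rng, n=60):
        a = rng.normal(0, 0.3, (n // 2, 2))
        b = rng.normal(0, 0.3, (n // 2, 2)) + 50.0
        return np.vstack([a, b]), np.repeat([0, 1], n // 2)

    def test_two_blobs_fully_recovered(self, rng):
        emb, truth = self._blob_embedding(rng)
        adj = build_snn_graph(emb, k=20)
        res = cluster_pixels(adj, resolution=0.9, seed=7)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_determinism_same_seed(self, rng):
        emb, _ = self._blob_embedding(rng)
        adj = build_snn_graph(emb, k=20)
        r1 = cluster_pixels(adj, resolution=0.9, seed=11)
        r2 = cluster_pixels(adj, resolution=0.9, seed=11)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_labels_contiguous_and_size_ordered(self, rng):
        emb, _ = self._blob_embedding(rng)
        adj = build_snn_graph(emb, k=5)
        res = cluster_pixels(adj, seed=3)
        sizes = [res.cluster_sizes[c] for c in sorted(res.cluster_sizes)]
        assert sorted(sizes, reverse=True) == sizes
        assert res.labels.min() == 1 and res.labels.max() == res.n_clusters
        assert sum(res.cluster_sizes.values()) == emb.shape[0]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            cluster_pixels(sparse.csr_matrix((0, 0)))

    def test_resolution_monotonicity_in_expectation(self, rng):
        """Mean cluster count at resolution 1.5 >= mean at 0.5 over seeds."""
        emb = rng.normal(0, 1, (150, 2))
        adj = build_snn_graph(emb, k=10)
        lo = [cluster_pixels(adj, 0.5, seed=s).n_clusters for s in range(20)]
        hi = [cluster_pixels(adj, 1.5, seed=s).n_clusters for s in range(20)]
        assert np.mean(hi) >= np.mean(lo)


class TestTopClusterLipids:
    def test_dominant_lipid_ranks_first(self, matrix_factory, rng):
        values = rng.uniform(1, 2, (60, 4))
        labels = np.repeat([1, 2, 3], 20)
        values[labels == 2, 3] *= 10.0
        df = top_cluster_lipids(matrix_factory(values), labels, n=2)
        top_c2 = df[(df.cluster == 2) & (df["rank"] == 1)]
        assert top_c2["feature_index"].iloc[0] == 3

    def test_matches_bruteforce_ranking(self, matrix_factory, rng):
        values = rng.lognormal(0, 1, (90, 12))
        values[rng.random((90, 12)) < 0.2] = 0
        labels = rng.integers(1, 4, 90)
        fm = matrix_factory(values)
        df = top_cluster_lipids(fm, labels, n=5)
        # brute-force oracle
        for c in np.unique(labels):
            mask = labels == c
            scores = {}
            for f in range(12):
                col = values[:, f]
                nz = col[col > 0]
                if nz.size == 0:
                    continue
                scores[f] = (col / np.median(nz))[mask].mean()
            expected = [f for f, _ in sorted(scores.items(), key=lambda kv: -kv[1])[:5]]
            got = df[df.cluster == c].sort_values("rank")["feature_index"].tolist()
            assert got == expected

    def test_single_cluster_equals_global_ranking(self, matrix_factory, rng):
        values = rng.lognormal(0, 1, (40, 6))
        fm = matrix_factory(values)
        one = top_cluster_lipids(fm, np.ones(40, dtype=int), n=3)
        assert one["cluster"].nunique() == 1

    def test_n_truncated_with_warning(self, matrix_factory, rng):
        values = rng.uniform(1, 2, (20, 3))
        with pytest.warns(UserWarning, match="truncat"):
            df = top_cluster_lipids(matrix_factory(values), np.ones(20, dtype=int), n=10)
        assert df["rank"].max() == 3


class TestAssignRegions:
    def _result(self):
        from msiregion import SegmentationResult

        labels = np.array([1, 1, 2, 2, 3])
        return SegmentationResult("s", labels, parameters={})

    def test_propagation(self):
        res = self._result()
        regions = assign_regions(res, {1: "airway_epithelium", 2: "alveolar_epithelium"})
        assert list(regions[:2]) == ["airway_epithelium"] * 2
        assert list(regions[2:4]) == ["alveolar_epithelium"] * 2

    def test_unmapped_cluster_unassigned(self):
        regions = assign_regions(self._result(), {1: "airway_epithelium"})
        assert regions[4] == "unassigned"

    def test_nonexistent_cluster_rejected(self):
        with pytest.raises(ValueError, match="non-existent"):
            assign_regions(self._result(), {9: "airway_epithelium"})

    def test_unknown_region_label_rejected(self):
        with pytest.raises(ValueError, match="region"):
            assign_regions(self._result(), {1: "spleen"})

    def test_only_mapped_regions_enter_statistics(self):
        """A map keeping only airway/alveolar epithelium leaves exactly those
        regions plus 'unassigned' for the rest."""
        res = self._result()
        regions = assign_regions(
            res, {1: "airway_epithelium", 2: "alveolar_epithelium"}
        )
        from msiregion.segment import NON_STATISTICAL_REGIONS

        statistical = {r for r in regions if r not in NON_STATISTICAL_REGIONS}
        assert statistical == {"airway_epithelium", "alveolar_epithelium"}
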