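"""Embeddings, clustering and the ANOVA/fold-change feature filter."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from phenomod.embedding import (
    DataMatrix,
    anova_feature_filter,
    cluster_features,
    hclust_cluster,
    kmeans_cluster,
    mds_embed,
    pca_embed,
    pca_som,
    som_fit,
    tsne_embed,
)
from phenomod.exceptions import ValidationError
from phenomod.simulate import simulate_clustered_matrix


def blobs(n_per, centers, sd, seed):
    rng = np.random.default_rng(seed)
    X = np.vstack([c + rng.normal(0, sd, (n_per, len(c))) for c in centers])
    labels = np.repeat(range(len(centers)), n_per)
    ids = [f"r{i}" for i in range(X.shape[0])]
    return DataMatrix(ids, [f"c{j}" for j in range(X.shape[1])], X), labels


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(25, 6))
    return DataMatrix([f"r{i}" for i in range(25)], [f"c{j}" for j in range(6)], X)


class TestPCA:
    def test_rank_one_data(self):
        X = np.array([[2.0, 1.0], [-2.0, -1.0], [4.0, 2.0], [-4.0, -2.0]])
        dm = DataMatrix(list("abcd"), ["x", "y"], X)
        res = pca_embed(dm, 1)
        assert res.extras["variance_explained"][0] == pytest.approx(1.0, abs=1e-12)
        v = res.extras["eigenvectors"][:, 0]
        expected = np.array([2.0, 1.0]) / np.sqrt(5.0)
        assert np.allclose(np.abs(v), np.abs(expected), atol=1e-12)

    def test_variance_explained_sums_to_one(self, random_matrix):
        res = pca_embed(random_matrix, 2)
        full = res.extras["variance_explained_full"]
        assert full.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(full) <= 1e-12)
        assert np.all((full >= 0) & (full <= 1))

    def test_scores_column_orthogonal(self, random_matrix):
        res = pca_embed(random_matrix, 4)
        S = res.coordinates
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.allclose(off, 0.0, atol=1e-8)

    def test_full_reconstruction(self, random_matrix):
        n_comp = min(random_matrix.n - 1, random_matrix.p)
        res = pca_embed(random_matrix, n_comp)
        recon = res.coordinates @ res.extras["eigenvectors"].T
        centered = random_matrix.values - random_matrix.values.mean(0)
        assert np.allclose(recon, centered, atol=1e-9)

    def test_loadings_are_correlations(self, random_matrix):
        res = pca_embed(random_matrix, 2)
        for j in range(random_matrix.p):
            for d in range(2):
                r = stats.pearsonr(random_matrix.values[:, j],
                                   res.coordinates[:, d])[0]
                assert res.extras["loadings"][j, d] == pytest.approx(r, abs=1e-9)

    def test_zero_variance_column_with_scaling_rejected(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        dm = DataMatrix([f"r{i}" for i in range(5)], ["flat", "ok"], X)
        with pytest.raises(ValidationError, match="flat"):
            pca_embed(dm, 1, scale=True)


class TestTSNE:
    def test_deterministic_given_seed(self):
        dm, _ = blobs(15, [(0, 0), (8, 8)], 1.0, 1)
        a = tsne_embed(dm, 2, perplexity=5, seed=42)
        b = tsne_embed(dm, 2, perplexity=5, seed=42)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_output_shape_3d(self):
        dm, _ = blobs(20, [(0, 0, 0), (5, 5, 5)], 1.0, 2)
        res = tsne_embed(dm, 3, perplexity=8, seed=0)
        assert res.coordinates.shape == (40, 3)

    def test_perplexity_range_enforced(self):
        dm, _ = blobs(5, [(0, 0), (5, 5)], 1.0, 3)
        with pytest.raises(ValidationError, match="perplexity"):
            tsne_embed(dm, 2, perplexity=10, seed=0)

    def test_separated_blobs_stay_separated(self):
        from sklearn.metrics import silhouette_score

        dm, labels = blobs(50, [(0, 0, 0), (10, 10, 0), (0, 10, 10)], 1.0, 4)
        res = tsne_embed(dm, 2, perplexity=20, seed=0)
        assert silhouette_score(res.coordinates, labels) > 0.5


class TestSOM:
    def test_four_tight_clusters_bijection(self):
        dm, labels = blobs(10, [(0, 0), (20, 0), (0, 20), (20, 20)], 0.2, 5)
        res = som_fit(dm, 2, 2, seed=1)
        assign = res.extras["assignment"]
        for node in np.unique(assign):
            assert len(set(labels[assign == node])) == 1
        assert len(np.unique(assign)) == 4

    def test_assignment_is_argmin_distance(self, random_matrix):
        res = som_fit(random_matrix, 3, 3, seed=2)
        code = res.extras["codebook"]
        d2 = ((random_matrix.values[:, None] - code[None]) ** 2).sum(-1)
        assert np.array_equal(res.extras["assignment"], d2.argmin(1))

    def test_deterministic(self, random_matrix):
        a = som_fit(random_matrix, 2, 3, seed=7)
        b = som_fit(random_matrix, 2, 3, seed=7)
        assert np.array_equal(a.extras["codebook"], b.extras["codebook"])

    def test_pca_som_composes(self, random_matrix):
        from phenomod.embedding.embed import pca_embed

        res = pca_som(random_matrix, 2, 2, 2, seed=3)
        scores = pca_embed(random_matrix, 2).coordinates
        reduced = DataMatrix(list(random_matrix.row_ids), ["PC1", "PC2"], scores)
        direct = som_fit(reduced, 2, 2, seed=3)
        assert np.array_equal(res.extras["codebook"], direct.extras["codebook"])

    def test_grid_larger_than_n_rejected(self, random_matrix):
        with pytest.raises(ValidationError):
            som_fit(random_matrix, 6, 6, seed=0)


class TestMDS:
    def test_points_on_line_dims1(self):
        X = np.column_stack([np.array([0.0, 1.0, 3.0, 7.0]), np.zeros(4)])
        dm = DataMatrix(list("abcd"), ["x", "y"], X)
        res = mds_embed(dm, 1)
        assert np.allclose(pdist(res.coordinates), pdist(X), atol=1e-9)

    def test_euclidean_2d_exact(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 2))
        dm = DataMatrix([f"r{i}" for i in range(12)], ["x", "y"], X)
        res = mds_embed(dm, 2)
        assert np.allclose(pdist(res.coordinates), pdist(X), atol=1e-6)

    def test_agrees_with_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 4))
        dm = DataMatrix([f"r{i}" for i in range(10)], list("wxyz"), X)
        res = mds_embed(dm, 2)
        ref = pcoa(np.ascontiguousarray(
            np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))), number_of_dimensions=2)
        assert np.allclose(np.abs(res.coordinates),
                           np.abs(ref.samples.to_numpy()), atol=1e-6)

    def test_correlated_rows_zero_distance(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 2.0]])
        dm = DataMatrix(list("abc"), list("xyz"), X)
        res = mds_embed(dm, 2, distance="correlation")
        assert np.linalg.norm(res.coordinates[0] - res.coordinates[1]) < 1e-6


class TestClustering:
    def test_two_separated_blobs_recovered(self):
        dm, labels = blobs(20, [(0, 0), (50, 50)], 1.0, 9)
        res = kmeans_cluster(dm, 2, seed=0)
        first = res.labels[labels == 0]
        second = res.labels[labels == 1]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_k1_wss_is_total_ss(self, random_matrix):
        res = kmeans_cluster(random_matrix, 1, seed=0)
        centered = random_matrix.values - random_matrix.values.mean(0)
        assert res.extras["wss"] == pytest.approx(float((centered**2).sum()))

    def test_wss_trace_non_increasing(self):
        dm, _ = blobs(25, [(0, 0), (4, 4), (8, 0)], 1.5, 10)
        res = kmeans_cluster(dm, 3, seed=1)
        trace = res.extras["wss_trace"]
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_kmeans_labels_contiguous_nonempty(self, random_matrix):
        res = kmeans_cluster(random_matrix, 4, seed=2)
        assert set(res.labels) == {1, 2, 3, 4}

    def test_k_greater_than_n_rejected(self, random_matrix):
        with pytest.raises(ValidationError):
            cluster_features(random_matrix, "kmeans", k=100, seed=0)

    def test_hclust_leaf_order_is_permutation(self, random_matrix):
        res = hclust_cluster(random_matrix, "average")
        assert sorted(res.extras["leaf_order"]) == list(range(random_matrix.n))
        assert sorted(res.extras["leaf_ids"]) == sorted(random_matrix.row_ids)

    def test_hclust_agrees_with_blob_structure(self):
        dm, labels = blobs(15, [(0, 0), (30, 30)], 1.0, 11)
        res = hclust_cluster(dm, "ward", k=2)
        assert len(set(res.labels[labels == 0])) == 1
        assert len(set(res.labels[labels == 1])) == 1


def brute_force_anova_p(columns):
    """Explicit sums-of-squares one-way F-test."""
    all_vals = np.concatenate(columns)
    grand = all_vals.mean()
    ss_between = sum(len(c) * (c.mean() - grand) ** 2 for c in columns)
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in columns)
    df1 = len(columns) - 1
    df2 = len(all_vals) - len(columns)
    F = (ss_between / df1) / (ss_within / df2)
    return float(stats.f.sf(F, df1, df2))


class TestAnovaFilter:
    def test_agrees_with_sums_of_squares_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(18, 15))
        dm = DataMatrix([f"r{i}" for i in range(18)],
                        [f"f{j}" for j in range(15)], X)
        groups = np.repeat(list("abc"), 6)
        res = anova_feature_filter(dm, groups, 0.5, 1.0, log2_scale=True)
        for j in range(15):
            cols = [X[groups == g, j] for g in "abc"]
            assert res.table["p_value"].iloc[j] == pytest.approx(
                brute_force_anova_p(cols), abs=1e-10)

    def test_strong_group_effect_selected(self):
        # group means (10, 10, 30), within-sd 1, n=5/group: huge F, FC=3
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(10, 1, 5), rng.normal(10, 1, 5),
                               rng.normal(30, 1, 5)])
        X = np.column_stack([vals, rng.normal(10, 1, 15)])
        dm = DataMatrix([f"r{i}" for i in range(15)], ["hit", "null"], X)
        groups = np.repeat(list("abc"), 5)
        res = anova_feature_filter(dm, groups, 0.05, 2.0)
        assert res.selected == ["hit"]

    def test_constant_feature_not_selected(self):
        rng = np.random.default_rng(14)
        X = np.column_stack([np.full(12, 7.0), rng.normal(5, 1, 12)])
        dm = DataMatrix([f"r{i}" for i in range(12)], ["const", "other"], X)
        res = anova_feature_filter(dm, np.repeat(list("ab"), 6), 0.05, 2.0)
        assert "const" not in res.selected
        assert res.table.loc["const", "fold_change"] == pytest.approx(1.0)

    def test_infinite_fc_threshold_empty(self):
        mat, truth = simulate_clustered_matrix(5, 2, 10, 2, effect=5.0, seed=1)
        res = anova_feature_filter(mat, truth["group_labels"], 0.05, np.inf,
                                   log2_scale=True)
        assert res.selected == []

    def test_monotone_in_both_thresholds(self):
        mat, truth = simulate_clustered_matrix(8, 3, 20, 3, effect=2.0, seed=2)
        groups = truth["group_labels"]
        loose = anova_feature_filter(mat, groups, 0.2, 1.2, log2_scale=True)
        tighter_p = anova_feature_filter(mat, groups, 0.01, 1.2, log2_scale=True)
        tighter_fc = anova_feature_filter(mat, groups, 0.2, 2.5, log2_scale=True)
        assert set(tighter_p.selected) <= set(loose.selected)
        assert set(tighter_fc.selected) <= set(loose.selected)

    def test_planted_features_recovered_exactly(self):
        mat, truth = simulate_clustered_matrix(30, 3, 30, 5, effect=10.0, seed=3)
        res = anova_feature_filter(mat, truth["group_labels"], 0.05, 2.0,
                                   log2_scale=True)
        assert sorted(res.selected) == sorted(sum(truth["planted"].values(), []))

    def test_small_group_rejected(self):
        rng = np.random.default_rng(15)
        dm = DataMatrix([f"r{i}" for i in range(5)], ["a", "b"],
                        rng.normal(size=(5, 2)))
        with pytest.raises(ValidationError, match="< 2"):
            anova_feature_filter(dm, ["x", "x", "x", "x", "y"], 0.05, 2.0)
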