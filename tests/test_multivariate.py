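import itertools

import numpy as np
import pandas as pd
import pytest

from schooldust.datamodel import ValidationError
from schooldust.multivariate import (
    hierarchical_cluster,
    kmeans_cluster,
    partitions_agree,
    pca_decomposition,
    pearson_matrix,
    select_k,
    zscore_standardize,
)


def blobs(rng, centers, n_per=8, sd=0.05):
    """Well-separated planted clusters with known labels."""
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sd, size=(n_per, len(c))))
        labels += [i + 1] * n_per
    X = np.vstack(pts)
    idx = [f"P{i}" for i in range(len(X))]
    return pd.DataFrame(X, index=idx), pd.Series(labels, index=idx)


class TestZScore:
    def test_forced_example(self):
        z = zscore_standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_moments(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, rtol=1e-12)

    def test_idempotent(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        np.testing.assert_allclose(zscore_standardize(z), z, atol=1e-10)

    def test_constant_column_names_element(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(ValidationError, match="b"):
            zscore_standardize(df)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        c = pearson_matrix(df)
        assert c.at["x", "up"] == pytest.approx(1.0)
        assert c.at["x", "down"] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_matches_direct_formula(self, rng):
        """Covariance over product of standard deviations, coded directly."""
        X = rng.normal(size=(24, 11))
        df = pd.DataFrame(X, columns=[f"e{i}" for i in range(11)])
        got = pearson_matrix(df).to_numpy()
        n = len(df)
        expect = np.empty((11, 11))
        for i, j in itertools.product(range(11), range(11)):
            xi, xj = X[:, i], X[:, j]
            cov = ((xi - xi.mean()) * (xj - xj.mean())).sum() / (n - 1)
            expect[i, j] = cov / (xi.std(ddof=1) * xj.std(ddof=1))
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_symmetry_and_range(self, default_dataset):
        c = pearson_matrix(default_dataset.conc.data)
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert (c.to_numpy() <= 1 + 1e-12).all() and (c.to_numpy() >= -1 - 1e-12).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            pearson_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestPCA:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=12)
        v = rng.normal(size=5)
        df = pd.DataFrame(np.outer(u, v))
        res = pca_decomposition(df)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_cumulative_variance_non_decreasing(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        res = pca_decomposition(z)
        cum = res.cumulative_variance
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] == pytest.approx(1.0)
        assert cum[2] > cum[1]  # 3 components explain more than 2

    def test_reconstruction_from_all_components(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        res = pca_decomposition(z)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy() + z.to_numpy().mean(axis=0)
        np.testing.assert_allclose(recon, z.to_numpy(), atol=1e-10)

    def test_loadings_orthonormal_scores_centred(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        res = pca_decomposition(z)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L @ L.T, np.eye(len(L)), atol=1e-10)
        np.testing.assert_allclose(res.scores.mean(), 0.0, atol=1e-10)

    def test_sign_convention(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        res = pca_decomposition(z)
        for _, row in res.loadings.iterrows():
            assert row.iloc[np.argmax(np.abs(row.to_numpy()))] > 0

    def test_n_components_bounds(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        with pytest.raises(ValidationError):
            pca_decomposition(z, n_components=12)


def brute_force_ward(X):
    """Exhaustive greedy Ward agglomeration, independent of scipy.

    Ward merge height between clusters A, B (scipy convention):
    sqrt(2 |A||B| / (|A|+|B|)) * ||mean_A - mean_B||.
    """
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma = X[clusters[a]].mean(axis=0)
            mb = X[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            h = np.sqrt(2.0 * na * nb / (na + nb)) * np.linalg.norm(ma - mb)
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        merges.append((h, frozenset(clusters[a]) | frozenset(clusters[b])))
        clusters[min(a, b)] = clusters.pop(a) + clusters.pop(b)
    return merges


class TestHierarchical:
    def test_duplicate_points_merge_first_at_zero(self):
        df = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]], index=list("abc"))
        res = hierarchical_cluster(df, n_clusters=2)
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_matches_exhaustive_ward_on_small_instances(self, rng):
        """Greedy Ward recomputed over all merge options, five points."""
        for _ in range(10):
            X = rng.normal(size=(5, 3))
            res = hierarchical_cluster(pd.DataFrame(X), n_clusters=2)
            oracle = brute_force_ward(X)
            np.testing.assert_allclose(
                res.linkage_matrix[:, 2], [h for h, _ in oracle], rtol=1e-9
            )

    def test_heights_non_decreasing(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        res = hierarchical_cluster(z, mode="elements", n_clusters=3)
        heights = res.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_planted_blobs_recovered(self, rng):
        df, truth = blobs(rng, [(0, 0), (10, 0), (0, 10)])
        res = hierarchical_cluster(df, n_clusters=3)
        assert partitions_agree(res.labels, truth)

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(pd.DataFrame([[1.0, 2.0]]), n_clusters=1)


class TestSelectK:
    def test_planted_blobs_select_three(self, rng):
        df, _ = blobs(rng, [(0, 0), (10, 0), (0, 10)])
        sel = select_k(df, k_range=range(2, 8), seed=0)
        assert sel.k_selected == 3
        assert ((sel.silhouette >= -1) & (sel.silhouette <= 1)).all()

    def test_wcss_non_increasing(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        sel = select_k(z, k_range=range(2, 8), seed=0)
        assert (np.diff(sel.wcss.to_numpy()) <= 1e-9 * sel.wcss.iloc[0]).all()

    def test_degenerate_input_rejected(self):
        df = pd.DataFrame(np.ones((6, 2)))
        with pytest.raises(ValidationError):
            select_k(df)


class TestKMeans:
    def test_seeded_determinism(self, default_dataset):
        z = zscore_standardize(default_dataset.conc)
        a = kmeans_cluster(z, 3, seed=11)
        b = kmeans_cluster(z, 3, seed=11)
        assert (a == b).all()

    def test_k_equals_n_zero_inertia(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 2)))
        labels = kmeans_cluster(df, 5, seed=0)
        assert len(set(labels)) == 5

    def test_k_above_n_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 2)))
        with pytest.raises(ValidationError):
            kmeans_cluster(df, 5, seed=0)

    def test_planted_blobs_recovered(self, rng):
        df, truth = blobs(rng, [(0, 0, 0), (8, 0, 0), (0, 8, 0)])
        labels = kmeans_cluster(df, 3, seed=0)
        assert partitions_agree(labels, truth)


class TestElementGroupRecovery:
    def test_hca_and_kmeans_agree_on_planted_groups(self, default_dataset):
        """Cutting the element dendrogram at 3 and k-means(3) both recover
        the planted traffic/construction/combustion element groups."""
        z = zscore_standardize(default_dataset.conc)
        truth = pd.Series(
            pd.factorize(pd.Series(default_dataset.element_groups))[0] + 1,
            index=default_dataset.conc.element_symbols,
        )
        hca = hierarchical_cluster(z, mode="elements", n_clusters=3)
        km = kmeans_cluster(z.T, 3, seed=0)
        assert partitions_agree(hca.labels, truth)
        assert partitions_agree(km, truth)
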