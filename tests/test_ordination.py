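"""Gower distances, PCoA, LDA, and the jackknifed ordination pipelines."""

import numpy as np
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

import phenobar as pb
from phenobar.errors import ComputationError, ValidationError
from phenobar.ordination import pcoa_project

from conftest import random_feature_matrix

AD, AP, AX = pb.ClassLabel.AD, pb.ClassLabel.AP, pb.ClassLabel.AX


def gower_bruteforce(values: np.ndarray) -> np.ndarray:
    """Independent double-loop oracle for the Gower distance."""
    n, p = values.shape
    rng_ = np.nanmax(values, axis=0) - np.nanmin(values, axis=0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = cnt = 0
            for c in range(p):
                if rng_[c] > 0 and np.isfinite(values[i, c]) \
                        and np.isfinite(values[j, c]):
                    num += abs(values[i, c] - values[j, c]) / rng_[c]
                    cnt += 1
            d[i, j] = num / cnt
    return d


class TestGower:
    def test_identical_rows_distance_zero(self):
        m = pb.FeatureMatrix(["a", "b", "c"], ["x", "y"],
                             np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 0.0]]))
        assert pb.gower_distance(m).values[0, 1] == 0.0

    def test_extremes_of_single_column_distance_one(self):
        m = pb.FeatureMatrix(["a", "b"], ["x"], np.array([[0.0], [7.0]]))
        assert pb.gower_distance(m).values[0, 1] == 1.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m = random_feature_matrix(rng, int(rng.integers(3, 8)),
                                      int(rng.integers(2, 6)),
                                      missing_rate=0.1)
            # guarantee every pair shares a column: make column 0 complete
            m.values[:, 0] = rng.normal(size=m.n_rows)
            got = pb.gower_distance(m).values
            np.testing.assert_allclose(got, gower_bruteforce(m.values),
                                       atol=1e-12)

    def test_disjoint_observation_pair_rejected(self):
        m = pb.FeatureMatrix(["a", "b", "c"], ["x", "y"],
                             np.array([[1.0, np.nan], [np.nan, 2.0],
                                       [0.5, 1.0]]))
        with pytest.raises(ComputationError, match="share no observed"):
            pb.gower_distance(m)


class TestPCoA:
    def test_recovers_planar_configuration(self):
        """Classical MDS on Euclidean distances reproduces the points up to
        an orthogonal transform."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 2))
        d = pb.DistanceMatrix([f"p{i}" for i in range(12)],
                              squareform(pdist(pts)), "other")
        res = pb.pcoa(d, m_axes=2)
        _, _, disparity = procrustes(pts, res.coordinates)
        assert disparity < 1e-8

    def test_matches_pca_scores(self):
        """PCoA of Euclidean distances equals PCA scores up to sign."""
        from sklearn.decomposition import PCA
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        d = pb.DistanceMatrix([f"p{i}" for i in range(10)],
                              squareform(pdist(X)), "other")
        res = pb.pcoa(d, m_axes=3)
        scores = PCA(n_components=3).fit_transform(X)
        for j in range(3):
            assert (np.allclose(res.coordinates[:, j], scores[:, j], atol=1e-8)
                    or np.allclose(res.coordinates[:, j], -scores[:, j],
                                   atol=1e-8))

    def test_matches_skbio_reference(self):
        """Independent cross-check against scikit-bio's PCoA."""
        from skbio.stats.ordination import pcoa as skbio_pcoa
        rng = np.random.default_rng(3)
        m = random_feature_matrix(rng, 8, 5)
        d = pb.gower_distance(m)
        ours = pb.pcoa(d)
        theirs = skbio_pcoa(d.values, method="eigh")
        ref = theirs.samples.to_numpy()[:, :ours.coordinates.shape[1]]
        for j in range(ours.coordinates.shape[1]):
            assert (np.allclose(ours.coordinates[:, j], ref[:, j], atol=1e-8)
                    or np.allclose(ours.coordinates[:, j], -ref[:, j],
                                   atol=1e-8))

    def test_one_dimensional_arrangement_single_axis(self):
        x = np.array([[0.0], [1.0], [2.0], [5.0]])
        d = pb.DistanceMatrix(list("abcd"), squareform(pdist(x)), "other")
        res = pb.pcoa(d)
        assert res.percent_of_total[0] == pytest.approx(100.0)

    def test_duplicated_point_identical_rows(self):
        x = np.array([[0.0, 0], [1, 1], [1, 1], [3, 0]])
        d = pb.DistanceMatrix(list("abcd"), squareform(pdist(x)), "other")
        res = pb.pcoa(d)
        np.testing.assert_allclose(res.coordinates[1], res.coordinates[2],
                                   atol=1e-10)

    def test_out_of_sample_projection_recovers_training_point(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(9, 3))
        D = squareform(pdist(pts))
        d = pb.DistanceMatrix([f"p{i}" for i in range(9)], D, "other")
        res = pb.pcoa(d, m_axes=3)
        proj = pcoa_project(D ** 2, res, D[4])
        np.testing.assert_allclose(proj, res.coordinates[4], atol=1e-8)


class TestLDA:
    def _blobs(self, sep=6.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, size=(n, 2)),
                       rng.normal(sep, 1, size=(n, 2))])
        y = [AD] * n + [AP] * n
        return X, y

    def test_separated_clusters_perfect_training_accuracy(self):
        X, y = self._blobs()
        model = pb.lda_fit(X, y)
        assert pb.lda_predict(model, X) == y

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError, match="2 classes"):
            pb.lda_fit(np.zeros((6, 2)), [AD] * 6)

    def test_centroids_predict_their_own_class(self):
        X, y = self._blobs(sep=4.0)
        model = pb.lda_fit(X, y)
        # class centroids in canonical space map back to their labels
        preds = []
        for c in model.class_labels:
            pts = np.array([x for x, l in zip(X, y) if l == c])
            preds += pb.lda_predict(model, pts.mean(axis=0, keepdims=True))
        assert preds == model.class_labels

    def test_too_many_axes_rejected(self):
        X, y = self._blobs(n=3)
        with pytest.raises((ValidationError, ComputationError)):
            pb.lda_fit(np.hstack([X] * 3)[:, :5], y)  # p > n - k


class TestJackknife:
    def test_separable_classes_score_100(self, prepped_drugs):
        res = pb.jackknife_pipeline(prepped_drugs, prepped_drugs.class_labels,
                                    "pcoa", m_axes=3)
        assert res.accuracy_jackknifed == 100.0

    def test_permuted_labels_drop_to_chance(self, prepped_drugs):
        rng = np.random.default_rng(5)
        labels = np.array(prepped_drugs.class_labels)
        accs = []
        for _ in range(20):
            perm = rng.permutation(len(labels))
            res = pb.jackknife_pipeline(prepped_drugs, list(labels[perm]),
                                        "pcoa", m_axes=3)
            accs.append(res.accuracy_jackknifed)
        assert abs(np.mean(accs) - 100 / 3) <= 15.0

    def test_minimal_input_runs(self):
        rng = np.random.default_rng(6)
        n, k = 5, 3  # n = k + 2
        m = random_feature_matrix(rng, n, 4)
        labels = [AD, AD, AP, AP, AX][:n]
        res = pb.jackknife_pipeline(m, labels, "pcoa", m_axes=2)
        assert 0 <= res.accuracy_jackknifed <= 100

    def test_jackknife_not_above_resubstitution(self, prepped_drugs):
        """LOO accuracy cannot systematically beat resubstitution."""
        res = pb.jackknife_pipeline(prepped_drugs, prepped_drugs.class_labels,
                                    "pcoa", m_axes=4)
        assert res.accuracy_jackknifed <= res.accuracy_unadjusted + 10.0

    def test_strict_mode_close_to_fast_on_clean_data(self, prepped_drugs):
        fast = pb.jackknife_pipeline(prepped_drugs, prepped_drugs.class_labels,
                                     "pcoa", m_axes=3, mode="fast")
        strict = pb.jackknife_pipeline(prepped_drugs, prepped_drugs.class_labels,
                                       "pcoa", m_axes=3, mode="strict")
        assert abs(fast.accuracy_jackknifed - strict.accuracy_jackknifed) <= 15.0

    def test_strict_umap_rejected(self, prepped_drugs):
        with pytest.raises(ValidationError, match="strict"):
            pb.jackknife_pipeline(prepped_drugs, prepped_drugs.class_labels,
                                  "umap", mode="strict", seed=0)


class TestSelectAxes:
    def test_signal_in_two_axes_selects_two(self):
        rng = np.random.default_rng(7)
        centers = {AD: (0, 0), AP: (8, 0), AX: (0, 8)}
        rows, labels = [], []
        for c, (cx, cy) in centers.items():
            rows.append(rng.normal((cx, cy), 1.0, size=(7, 2)))
            labels += [c] * 7
        X = np.hstack([np.vstack(rows), rng.normal(scale=0.5, size=(21, 4))])
        m = pb.FeatureMatrix([f"r{i}" for i in range(21)],
                             [f"c{j}" for j in range(6)], X)
        m_best, res = pb.select_pcoa_axes(m, labels, range(2, 7))
        assert m_best == 2 and res.accuracy_jackknifed >= 90.0

    def test_tie_breaks_to_smallest_m(self, prepped_drugs):
        m_best, _ = pb.select_pcoa_axes(prepped_drugs,
                                        prepped_drugs.class_labels,
                                        range(3, 7))
        results = {m: pb.jackknife_pipeline(prepped_drugs,
                                            prepped_drugs.class_labels,
                                            "pcoa", m_axes=m).accuracy_jackknifed
                   for m in range(3, 7)}
        best_acc = max(results.values())
        assert m_best == min(m for m, a in results.items() if a == best_acc)

    def test_single_m_range(self, prepped_drugs):
        m_best, _ = pb.select_pcoa_axes(prepped_drugs,
                                        prepped_drugs.class_labels, [4])
        assert m_best == 4

    def test_empty_range_rejected(self, prepped_drugs):
        with pytest.raises(ValidationError):
            pb.select_pcoa_axes(prepped_drugs, prepped_drugs.class_labels, [])


class TestUMAP:
    @pytest.fixture(scope="class")
    def cluster_distance(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 0.3, size=(10, 3)),
                       rng.normal(5, 0.3, size=(10, 3))])
        d = squareform(pdist(X))
        d /= d.max()
        return (pb.DistanceMatrix([f"p{i}" for i in range(20)], d, "gower"),
                [AD] * 10 + [AP] * 10)

    def test_same_seed_identical_embedding(self, cluster_distance):
        d, _ = cluster_distance
        a = pb.umap_embed(d, n_neighbors=5, seed=3)
        b = pb.umap_embed(d, n_neighbors=5, seed=3)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_n_neighbors_bound(self, cluster_distance):
        d, _ = cluster_distance
        with pytest.raises(ValidationError):
            pb.umap_embed(d, n_neighbors=20, seed=0)

    def test_separated_clusters_good_silhouette(self, cluster_distance):
        d, labels = cluster_distance
        grid = [{"n_neighbors": 5, "min_dist": 0.1},
                {"n_neighbors": 8, "min_dist": 0.5}]
        params, _emb, sil = pb.umap_param_search(d, labels, grid, seed=1)
        assert sil > 0.5
        assert params in grid

    def test_empty_grid_rejected(self, cluster_distance):
        d, labels = cluster_distance
        with pytest.raises(ValidationError):
            pb.umap_param_search(d, labels, [], seed=0)
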