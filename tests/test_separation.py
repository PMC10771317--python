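import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from numts import separation


def _fm(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)


class TestPreprocess:
    def test_constant_row_dropped(self):
        m = _fm([[1, 1, 1], [0, 1, 3]])
        with pytest.warns(UserWarning, match="constant"):
            out = separation.preprocess_lcs(m)
        assert list(out.index) == ["f1"]

    def test_row_log_center_scale(self):
        out = separation.preprocess_lcs(_fm([[0, 1, 3]]))
        # log2(x+1) gives (0, 1, 2); centered/scaled to mean 0, sd 1
        expected = (np.array([0, 1, 2]) - 1) / np.std([0, 1, 2])
        assert np.allclose(out.to_numpy()[0], expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_rows_have_zero_mean_unit_sd(self, seed):
        rng = np.random.default_rng(seed)
        out = separation.preprocess_lcs(_fm(rng.uniform(0, 100, (20, 15))))
        assert np.allclose(out.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.to_numpy().std(axis=1), 1, atol=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            separation.preprocess_lcs(_fm([[-1, 0, 1]]))


class TestHierarchicalCluster:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, (5, 10))
        b = rng.normal(6, 0.2, (5, 10))
        m = _fm(np.hstack([a, b]))
        labels, _ = separation.hierarchical_cluster(m, k=2)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        m = _fm(rng.uniform(size=(4, 6)))
        labels, _ = separation.hierarchical_cluster(m, k=6)
        assert len(set(labels)) == 6

    def test_duplicate_columns_cluster_together(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(size=(5, 1))
        rest = rng.uniform(10, 20, (5, 4))
        m = _fm(np.hstack([col, col, rest]))
        labels, _ = separation.hierarchical_cluster(m, k=3)
        assert labels.iloc[0] == labels.iloc[1]

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            separation.hierarchical_cluster(_fm(np.eye(3)), k=4)


class TestPca:
    def test_collinear_data_is_rank_one(self):
        t = np.linspace(0, 1, 10)
        m = _fm(np.vstack([2 * t, -3 * t, 5 * t]))
        scores, explained = separation.pca_project(m, n_components=1)
        assert explained[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        m = _fm(rng.uniform(size=(5, 10)))
        scores, explained = separation.pca_project(m, n_components=2)
        X = m.to_numpy().T
        X = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        for j in range(2):
            ref = X @ evecs[:, j]
            got = scores.iloc[:, j].to_numpy()
            assert np.allclose(np.abs(got), np.abs(ref), atol=1e-9)
        assert np.allclose(explained, (evals / evals.sum())[:2], atol=1e-12)

    def test_isotropic_gaussian_equal_fractions(self):
        rng = np.random.default_rng(4)
        m = _fm(rng.standard_normal((2, 2000)))
        _, explained = separation.pca_project(m, n_components=2)
        assert abs(explained[0] - 0.5) < 0.05

    def test_components_beyond_rank_error(self):
        t = np.linspace(0, 1, 8)
        m = _fm(np.vstack([t, 2 * t]))
        with pytest.raises(ValueError, match="rank"):
            separation.pca_project(m, n_components=2)


class TestBetweenGroupRate:
    def test_hand_computed_two_group_fixture(self):
        # one feature, A = {0, 2}, B = {4, 6}: SS_between 16, SS_total 20
        m = _fm([[0, 2, 4, 6]])
        labels = pd.Series(["A", "A", "B", "B"], index=m.columns)
        assert separation.between_group_rate(m, labels) == pytest.approx(80.0)

    def test_equal_group_means_near_zero(self):
        rng = np.random.default_rng(5)
        m = _fm(rng.standard_normal((10, 200)))
        labels = pd.Series(["A"] * 100 + ["B"] * 100, index=m.columns)
        assert separation.between_group_rate(m, labels) < 5.0

    def test_fully_separated_groups_reach_100(self):
        m = _fm([[1, 1, 5, 5]])
        labels = pd.Series(["A", "A", "B", "B"], index=m.columns)
        assert separation.between_group_rate(m, labels) == pytest.approx(100.0)

    def test_invariant_to_feature_rescaling(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(size=(4, 30))
        base[:, 15:] += 1.0
        m = _fm(base)
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=m.columns)
        r1 = separation.between_group_rate(m, labels)
        scaled = _fm(base * np.array([[10], [0.1], [3], [7]]))
        r2 = separation.between_group_rate(scaled, labels)
        assert r1 == pytest.approx(r2)


class TestMahalanobis:
    def _scores(self, arrays, groups):
        X = np.vstack(arrays)
        idx = [f"s{i}" for i in range(len(X))]
        labels = pd.Series(
            [g for g, a in zip(groups, arrays) for _ in range(len(a))],
            index=idx)
        return pd.DataFrame(X, index=idx, columns=["PC1", "PC2"]), labels

    def test_identical_centroids_distance_zero(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((30, 2))
        b = 2 * a.mean(axis=0) - a  # reflected: identical sample centroid
        scores, labels = self._scores([a, b], ["A", "B"])
        d = separation.mahalanobis_group_distance(scores, labels)
        assert d.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)

    def test_whitened_case_equals_euclidean(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((4000, 2))
        b = rng.standard_normal((4000, 2)) + np.array([3.0, 0.0])
        scores, labels = self._scores([a, b], ["A", "B"])
        d = separation.mahalanobis_group_distance(scores, labels)
        centroid_dist = np.linalg.norm(a.mean(0) - b.mean(0))
        assert d.loc["A", "B"] == pytest.approx(centroid_dist, rel=0.05)

    def test_matches_closed_form_on_2d_fixture(self):
        rng = np.random.default_rng(9)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        a = rng.standard_normal((40, 2)) @ L.T
        b = rng.standard_normal((40, 2)) @ L.T + np.array([2.0, -1.0])
        scores, labels = self._scores([a, b], ["A", "B"])
        d = separation.mahalanobis_group_distance(scores, labels)
        Sa, Sb = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
        pooled = (39 * Sa + 39 * Sb) / 78
        delta = a.mean(0) - b.mean(0)
        det = pooled[0, 0] * pooled[1, 1] - pooled[0, 1] ** 2
        inv = np.array([[pooled[1, 1], -pooled[0, 1]],
                        [-pooled[1, 0], pooled[0, 0]]]) / det
        expected = float(np.sqrt(delta @ inv @ delta))
        assert d.loc["A", "B"] == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_affine_transform(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((50, 2))
        b = rng.standard_normal((50, 2)) + 2.0
        scores, labels = self._scores([a, b], ["A", "B"])
        d1 = separation.mahalanobis_group_distance(scores, labels)
        A = np.array([[3.0, 1.0], [0.5, 2.0]])
        t_scores = scores.copy()
        t_scores.iloc[:] = scores.to_numpy() @ A.T + np.array([5.0, -2.0])
        d2 = separation.mahalanobis_group_distance(t_scores, labels)
        assert d1.loc["A", "B"] == pytest.approx(d2.loc["A", "B"], rel=1e-9)

    def test_small_group_errors(self):
        scores = pd.DataFrame(np.eye(4)[:, :2],
                              index=list("wxyz"), columns=["PC1", "PC2"])
        labels = pd.Series(["A", "A", "B", "B"], index=scores.index)
        with pytest.raises(ValueError, match="samples"):
            separation.mahalanobis_group_distance(scores, labels)
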