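import numpy as np
import pytest

from mrhabitats.cluster import (
    HabitatMixture,
    build_region_map,
    mean_cluster_curves,
    relabel_by_dce_auc,
)
from mrhabitats.containers import DeltaR1Matrix, FeatureSet


def feature_set(X, names=None):
    n = X.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    names = names or [f"f{j}" for j in range(X.shape[1])]
    return FeatureSet(matrix=X, names=names, coords=coords, tumor_ids=np.zeros(n, int))


def blobs(rng, means, n_per=200, sd=1.0):
    X = np.vstack([rng.normal(m, sd, size=(n_per, len(means[0]))) for m in means])
    truth = np.repeat(np.arange(1, len(means) + 1), n_per)
    return X, truth


class TestFit:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X, truth = blobs(rng, [(0.0, 0.0), (10.0, 10.0)], sd=1.0)  # 10 SD apart
        fs = feature_set(X)
        res = HabitatMixture(fs, auc_dce=X[:, 0]).fit(2, random_state=1)
        acc = np.mean(res.labels == truth)
        assert acc >= 0.999
        # fitted means agree with the sample means of the generating
        # components to within 0.05 of the component SD
        sample_means = np.vstack([X[truth == 1].mean(0), X[truth == 2].mean(0)])
        assert np.max(np.abs(res.means - sample_means)) < 0.05

    def test_single_component_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 3))
        res = HabitatMixture(feature_set(X)).fit(1, n_restarts=1, random_state=0)
        assert np.allclose(res.means[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(res.covariances[0], np.cov(X, rowvar=False, ddof=0), atol=1e-4)
        assert res.weights[0] == pytest.approx(1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X, _ = blobs(rng, [(0, 0), (6, 6), (12, 0)], n_per=100)
        fs = feature_set(X)
        a = HabitatMixture(fs).fit(3, random_state=5)
        b = HabitatMixture(fs).fit(3, random_state=5)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.means, b.means)

    def test_duplicated_data_doubles_loglik(self):
        rng = np.random.default_rng(3)
        X, _ = blobs(rng, [(0, 0), (10, 10)], n_per=150)
        fs1, fs2 = feature_set(X), feature_set(np.vstack([X, X]))
        r1 = HabitatMixture(fs1, auc_dce=fs1.matrix[:, 0]).fit(2, random_state=0)
        r2 = HabitatMixture(fs2, auc_dce=fs2.matrix[:, 0]).fit(2, random_state=0)
        assert np.allclose(r2.means, r1.means, atol=0.05)
        assert r2.llf == pytest.approx(2 * r1.llf, rel=1e-3)

    def test_nested_loglik_monotone_in_n_clusters(self):
        rng = np.random.default_rng(4)
        X, _ = blobs(rng, [(0, 0), (8, 8)], n_per=150)
        model = HabitatMixture(feature_set(X))
        lls = [model.fit(k, random_state=0).llf for k in (1, 2, 3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1.0  # small tolerance: finite restarts

    def test_labels_maximize_responsibility(self):
        rng = np.random.default_rng(5)
        X, _ = blobs(rng, [(0, 0), (4, 4)], n_per=100)
        res = HabitatMixture(feature_set(X)).fit(2, random_state=0)
        assert np.array_equal(res.labels, np.argmax(res.responsibilities, axis=1) + 1)
        assert np.allclose(res.responsibilities.sum(axis=1), 1.0)
        assert res.weights.sum() == pytest.approx(1.0)

    def test_invalid_cluster_counts_rejected(self):
        X = np.random.default_rng(6).normal(size=(30, 2))
        model = HabitatMixture(feature_set(X))
        with pytest.raises(ValueError):
            model.fit(26)
        with pytest.raises(ValueError):
            model.fit(30)


class TestRelabel:
    def make_result(self, cluster_aucs, n_per=50, seed=0):
        """Fit on 1-D blobs positioned at the requested AUC means."""
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal([m, 0.0], 0.01, size=(n_per, 2)) for m in cluster_aucs]
        )
        fs = feature_set(X, names=["AUC_DCE", "f1"])
        return HabitatMixture(fs).fit(len(cluster_aucs), random_state=1), X

    def test_permutation_sorts_by_mean_auc(self):
        res, X = self.make_result([5.0, 1.0, 3.0])
        out = relabel_by_dce_auc(res, X[:, 0])
        means = [np.mean(X[out.labels == j, 0]) for j in (1, 2, 3)]
        assert means == sorted(means)
        # clusters generated at AUC (5, 1, 3) -> new labels (3, 1, 2)
        assert list(out.labels[[0, 50, 100]]) == [3, 1, 2]

    def test_idempotent_and_identity_when_ordered(self):
        res, X = self.make_result([1.0, 2.0, 3.0])
        once = relabel_by_dce_auc(res, X[:, 0])
        twice = relabel_by_dce_auc(once, X[:, 0])
        assert np.array_equal(once.labels, twice.labels)
        assert np.allclose(once.means, twice.means)

    def test_relabeling_preserves_likelihood_and_aic(self):
        res, X = self.make_result([4.0, 0.0])
        out = relabel_by_dce_auc(res, X[:, 0])
        assert out.llf == res.llf
        assert out.aic == res.aic
        # same partition, possibly renamed
        assert np.array_equal(out.labels == out.labels[0], res.labels == res.labels[0])

    def test_fit_applies_canonical_order_automatically(self):
        rng = np.random.default_rng(7)
        X = np.vstack(
            [rng.normal([m, 0.0], 0.05, size=(60, 2)) for m in (9.0, -3.0, 2.0)]
        )
        fs = feature_set(X, names=["AUC_DCE", "AUC_OE"])
        res = HabitatMixture(fs).fit(3, random_state=0)
        cluster_means = [np.mean(X[res.labels == j, 0]) for j in (1, 2, 3)]
        assert cluster_means == sorted(cluster_means)


class TestRegionMap:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(8)
        grid = (6, 5, 4)
        coords = np.argwhere(np.ones(grid, bool))
        labels = rng.integers(1, 4, size=coords.shape[0])
        rmap = build_region_map(labels, coords, grid)
        assert np.array_equal(rmap.labels[tuple(coords.T)], labels)

    def test_single_voxel_and_checker_pattern(self):
        rmap = build_region_map(np.array([2]), np.array([[1, 1, 1]]), (3, 3, 3))
        assert rmap.labels.sum() == 2
        grid = (4, 4, 2)
        coords = np.argwhere(np.ones(grid, bool))
        checker = 1 + (coords.sum(axis=1) % 2)
        rmap = build_region_map(checker, coords, grid)
        assert np.array_equal(rmap.labels[tuple(coords.T)], checker)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError):
            build_region_map(
                np.array([1, 2]), np.array([[0, 0, 0], [0, 0, 0]]), (2, 2, 2)
            )

    def test_off_mask_is_zero(self):
        rmap = build_region_map(np.array([3]), np.array([[0, 0, 0]]), (2, 2, 2))
        assert rmap.labels[0, 0, 0] == 3
        assert (rmap.labels != 0).sum() == 1


class TestMeanClusterCurves:
    def make_pair(self, values):
        n = values.shape[0]
        coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
        m = DeltaR1Matrix(
            values=values, frame_times=np.arange(values.shape[1]) * 5.0,
            event_frame=1, coords=coords, modality="DCE",
        )
        m2 = DeltaR1Matrix(
            values=values.copy(), frame_times=m.frame_times,
            event_frame=1, coords=coords, modality="OE",
        )
        return m, m2

    def fit_two(self, X):
        fs = feature_set(X)
        return HabitatMixture(fs, auc_dce=X[:, 0]).fit(2, random_state=0)

    def test_symmetric_curves_average_to_zero(self):
        c = np.linspace(0, 1, 8)
        values = np.vstack([c, -c, c + 10, -c + 10])
        X = np.array([[0.0, 0], [0.1, 0], [10.0, 0], [10.1, 0]])
        res = self.fit_two(X)
        dce, oe = self.make_pair(values)
        curves = mean_cluster_curves(res, dce, oe)
        g = curves[(curves.modality == "DCE") & (curves.cluster == 1)]
        assert np.allclose(g.mean_dr1, 0.0, atol=1e-12)

    def test_single_member_cluster_sem_zero(self):
        values = np.vstack([np.zeros(8), np.ones(8), np.ones(8)])
        X = np.array([[0.0, 0], [10.0, 0], [10.1, 0]])
        fs = feature_set(X)
        res = HabitatMixture(fs, auc_dce=X[:, 0]).fit(2, random_state=0)
        dce, oe = self.make_pair(values)
        curves = mean_cluster_curves(res, dce, oe)
        singleton = curves[(curves.n_voxels == 1)]
        assert not singleton.empty
        assert np.all(singleton.sem_dr1 == 0)

    def test_phantom_cluster_means_match_templates(self, clean_phantom, clean_delta_r1):
        """On a noiseless phantom the mean within-cluster curves reproduce
        the injected habitat kinetics."""
        from mrhabitats.features import auc_features

        dce, oe = clean_delta_r1
        fs = auc_features(dce, oe)
        res = HabitatMixture(fs).fit(3, random_state=0)
        curves = mean_cluster_curves(res, dce, oe)
        # habitats are ordered by DCE enhancement: core < shell < rim
        order = ["necrotic_core", "hypoxic_shell", "perfused_rim"]
        for j, name in enumerate(order, start=1):
            g = curves[(curves.modality == "DCE") & (curves.cluster == j)]
            truth = clean_phantom.truth_curves[name]["dce"]
            assert np.allclose(g.sort_values("frame").mean_dr1.to_numpy(), truth, atol=1e-7)
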