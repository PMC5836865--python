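import itertools
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from mrhabitats.cluster import HabitatMixture, build_region_map
from mrhabitats.containers import FeatureSet, RegionMap
from mrhabitats.evaluate import (
    EvaluationReport,
    contiguity_zscore,
    count_connected_regions,
    hungarian_match,
    select_optimum,
    silhouette_values,
    stability_analysis,
)


def feature_set(X):
    n = X.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    return FeatureSet(
        matrix=X, names=[f"f{j}" for j in range(X.shape[1])],
        coords=coords, tumor_ids=np.zeros(n, int),
    )


def flood_fill_count(volume):
    """Independent 26-connectivity component counter (BFS flood fill)."""
    volume = np.asarray(volume)
    visited = np.zeros(volume.shape, dtype=bool)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    count = 0
    nx, ny, nz = volume.shape
    for start in zip(*np.nonzero(volume)):
        if visited[start]:
            continue
        lab = volume[start]
        count += 1
        q = deque([start])
        visited[start] = True
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                u, v, w = x + dx, y + dy, z + dz
                if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz:
                    if not visited[u, v, w] and volume[u, v, w] == lab:
                        visited[u, v, w] = True
                        q.append((u, v, w))
    return count


@dataclass
class FakeResult:
    n_clusters: int
    d: int
    llf: float

    @property
    def n_features(self):
        return self.d

    @property
    def n_free_parameters(self):
        k, d = self.n_clusters, self.d
        return k * d + k * d * (d + 1) // 2 + (k - 1)

    @property
    def aic(self):
        return 2.0 * self.n_free_parameters - 2.0 * self.llf


class TestAic:
    @pytest.mark.parametrize(
        "nc,d,k", [(1, 2, 5), (6, 4, 89), (2, 2, 11), (6, 2, 35)]
    )
    def test_free_parameter_count(self, nc, d, k):
        assert FakeResult(nc, d, 0.0).n_free_parameters == k

    def test_aic_arithmetic(self):
        assert FakeResult(1, 2, -100.0).aic == 210.0

    def test_aic_decreases_with_likelihood_at_fixed_k(self):
        assert FakeResult(3, 2, -50.0).aic < FakeResult(3, 2, -80.0).aic


class TestConnectedRegions:
    def test_solid_ellipsoid_is_one_region(self):
        x, y, z = np.meshgrid(*[np.arange(12)] * 3, indexing="ij")
        ell = (((x - 6) / 5) ** 2 + ((y - 6) / 4) ** 2 + ((z - 6) / 3) ** 2) <= 1
        assert count_connected_regions(ell.astype(int)) == 1

    def test_diagonal_voxels_joined_by_26_connectivity(self):
        vol = np.zeros((3, 3, 3), dtype=int)
        vol[0, 0, 0] = vol[1, 1, 1] = 1
        assert count_connected_regions(vol) == 1

    def test_empty_map_counts_zero(self):
        assert count_connected_regions(np.zeros((4, 4, 4), dtype=int)) == 0

    def test_matches_flood_fill_oracle_on_random_volumes(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vol = rng.integers(0, 7, size=(10, 10, 10))
            assert count_connected_regions(vol) == flood_fill_count(vol)


class TestContiguityZ:
    def rim_core_map(self, n=10, three=False):
        x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        c = (n - 1) / 2
        rho = np.sqrt(((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)) / (c + 0.5)
        labels = np.zeros((n, n, n), dtype=int)
        labels[rho <= 1] = 3 if three else 2
        if three:
            labels[rho <= 0.75] = 2
        labels[rho <= 0.5] = 1
        return RegionMap(labels=labels)

    def test_structured_map_scores_high(self):
        # with a 26-connected kernel the label-shuffle null is itself quite
        # contiguous for two balanced labels, so the three-shell map is the
        # structured case that clearly separates from chance
        z = contiguity_zscore(self.rim_core_map(three=True), n_boot=100, seed=0)
        assert z > 3
        z2 = contiguity_zscore(self.rim_core_map(), n_boot=100, seed=0)
        assert z2 > 0  # two-label map: more contiguous than chance, weaker z

    def test_randomized_map_scores_near_zero(self):
        rmap = self.rim_core_map()
        rng = np.random.default_rng(1)
        shuffled = rmap.labels.copy()
        vals = shuffled[shuffled > 0]
        shuffled[shuffled > 0] = rng.permutation(vals)
        z = contiguity_zscore(RegionMap(labels=shuffled), n_boot=100, seed=2)
        assert abs(z) < 3

    def test_seeded_determinism(self):
        rmap = self.rim_core_map(8)
        a = contiguity_zscore(rmap, n_boot=50, seed=3)
        b = contiguity_zscore(rmap, n_boot=50, seed=3)
        assert a == b

    def test_label_permutation_invariance(self):
        rmap = self.rim_core_map(8)
        swapped = rmap.labels.copy()
        swapped[rmap.labels == 1] = 2
        swapped[rmap.labels == 2] = 1
        a = contiguity_zscore(rmap, n_boot=80, seed=4)
        b = contiguity_zscore(RegionMap(labels=swapped), n_boot=80, seed=4)
        assert a == pytest.approx(b, abs=0.7)  # same structure, same null family

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            contiguity_zscore(RegionMap(labels=np.ones((4, 4, 4), dtype=int)))


class TestHungarian:
    def test_identical_sets_identity_zero_cost(self):
        a = np.arange(12.0).reshape(4, 3)
        perm, cost = hungarian_match(a, a)
        assert np.array_equal(perm, np.arange(4))
        assert cost == 0.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(5)
        for k in (2, 3, 4, 5):
            a = rng.normal(size=(k, 3))
            b = rng.normal(size=(k, 3))
            perm, cost = hungarian_match(a, b)
            best = min(
                sum(np.linalg.norm(a[i] - b[p[i]]) for i in range(k))
                for p in itertools.permutations(range(k))
            )
            assert cost == pytest.approx(best, rel=1e-12)

    def test_row_swap_compensated(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        _, cost = hungarian_match(a, b)
        b2 = b[[1, 0, 2, 3]]
        perm2, cost2 = hungarian_match(a, b2)
        assert cost2 == pytest.approx(cost, rel=1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            hungarian_match(np.zeros((3, 2)), np.zeros((4, 2)))


class TestSilhouettes:
    def test_separated_groups_near_one(self):
        rng = np.random.default_rng(7)
        pts = np.vstack(
            [rng.normal(0, 0.01, (20, 2)), rng.normal(100, 0.01, (20, 2))]
        )
        s = silhouette_values(pts, np.repeat([0, 1], 20))
        assert np.all(s > 0.99)

    def test_four_point_hand_instance(self):
        # points (0,0),(0,1) label A and (4,0),(4,1) label B:
        # a = 1, b = (4 + sqrt(17)) / 2, s = (b - a)/b for every point
        pts = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]])
        s = silhouette_values(pts, np.array([0, 0, 1, 1]))
        assert np.allclose(s, 0.7537887487646789, atol=1e-12)

    def test_identical_points_score_zero(self):
        pts = np.zeros((6, 2))
        s = silhouette_values(pts, np.repeat([0, 1], 3))
        assert np.all(s == 0)

    def test_singleton_label_scores_zero(self):
        pts = np.array([[0.0, 0], [1, 0], [10, 0]])
        s = silhouette_values(pts, np.array([0, 0, 1]))
        assert s[2] == 0.0

    def test_bounds_and_isometry_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(40, 3))
        labels = rng.integers(0, 3, size=40)
        s = silhouette_values(pts, labels)
        assert np.all((s >= -1) & (s <= 1))
        # rotation + translation leaves silhouettes unchanged
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        s2 = silhouette_values(pts @ q + 5.0, labels)
        assert np.allclose(s, s2, atol=1e-10)

    def test_matches_sklearn_on_generic_data(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(50, 2))
        labels = rng.integers(0, 3, size=50)
        assert np.allclose(
            silhouette_values(pts, labels), silhouette_samples(pts, labels), atol=1e-10
        )

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            silhouette_values(np.zeros((3, 2)), np.zeros(3))


class TestStability:
    def test_separated_clusters_perfectly_stable(self):
        rng = np.random.default_rng(10)
        X = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(50, 1, (150, 2))])
        scores, _ = stability_analysis(
            feature_set(X), [2], n_boot=15, n_restarts=4, seed=0
        )
        assert np.median(scores[2]) > 0.95

    def test_structureless_data_less_stable_when_overclustered(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(400, 2))  # single Gaussian, no cluster structure
        scores, _ = stability_analysis(
            feature_set(X), [4], n_boot=15, n_restarts=4, seed=1
        )
        assert np.median(scores[4]) < 0.6

    def test_identity_bootstrap_reproduces_reference(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(30, 1, (100, 2))])
        fs = feature_set(X)
        model = HabitatMixture(fs)
        ref = {2: model.fit(2, n_restarts=4, random_state=7)}
        scores, fits = stability_analysis(
            fs, [2], n_boot=1, n_restarts=4, seed=7, reference=ref,
            index_sampler=lambda rng, n: np.arange(n),
        )
        boot_model = HabitatMixture(fs).fit(2, n_restarts=4, random_state=None)
        # the lone realization's matched centers coincide with the reference
        # up to EM determinism on the identical sample
        perm, cost = hungarian_match(ref[2].means, boot_model.means)
        assert cost < 0.5


class TestSelectOptimum:
    def make_report(self, rows):
        return EvaluationReport(
            table=pd.DataFrame(
                rows, columns=["feature_set", "n_clusters", "aic", "median_stability", "median_contiguity_z"]
            )
        )

    def test_reproduces_reference_metric_pattern(self):
        # stability collapses above 4 clusters for the AUC set and above 6
        # for the PCA set; the rule picks the PCA set with 6 clusters
        rows = []
        for nc in range(2, 9):
            rows.append(("auc", nc, 1000.0 - nc, 0.95 if nc <= 4 else 0.5, 5.0))
            rows.append(("pca", nc, 900.0 - nc, 0.95 if nc <= 6 else 0.5, 5.0))
        report = self.make_report(rows)
        assert select_optimum(report) == ("pca", 6)
        assert report.trace

    def test_tie_broken_toward_lower_aic(self):
        rows = [("auc", 3, 500.0, 0.9, 5.0), ("pca", 3, 400.0, 0.9, 5.0)]
        report = self.make_report(rows)
        assert select_optimum(report) == ("pca", 3)

    def test_fallback_when_nothing_passes_contiguity(self):
        rows = [("auc", 2, 500.0, 0.9, 1.0), ("auc", 3, 400.0, 0.85, 0.5)]
        report = self.make_report(rows)
        with pytest.warns(UserWarning):
            assert select_optimum(report) == ("auc", 3)

    def test_fallback_when_nothing_stable(self):
        rows = [("auc", 2, 500.0, 0.5, 1.0), ("auc", 3, 400.0, 0.3, 0.5)]
        report = self.make_report(rows)
        with pytest.warns(UserWarning):
            assert select_optimum(report) == ("auc", 2)
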