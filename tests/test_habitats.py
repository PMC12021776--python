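"""Voxel clustering, Calinski-Harabasz selection and enhancement ordering."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from habikit.habitats import (
    build_voxel_vectors,
    calinski_harabasz,
    compute_habitats,
    kmeans,
    order_subregions,
    select_k,
)


class TestVoxelVectors:
    def test_row_count_and_roundtrip(self, tiny_case):
        vfm = build_voxel_vectors(tiny_case)
        assert vfm.matrix.shape == (tiny_case.n_mask_voxels, 2)
        # scatter back reproduces the masked volumes exactly
        back_a = vfm.scatter(vfm.matrix[:, 0], fill=-50.0)
        np.testing.assert_array_equal(
            back_a[tiny_case.mask > 0], tiny_case.arterial[tiny_case.mask > 0]
        )

    def test_constant_phases_identical_rows(self):
        from habikit.preprocessing import DualPhaseCase, ImageGrid

        shape = (3, 4, 4)
        mask = np.ones(shape, dtype=np.uint8)
        case = DualPhaseCase(
            np.full(shape, 10.0), np.full(shape, 20.0), mask, ImageGrid(shape, (5, 1, 1))
        )
        vfm = build_voxel_vectors(case)
        assert np.all(vfm.matrix == [10.0, 20.0])


class TestKMeans:
    def test_two_point_masses_split_perfectly(self):
        X = np.array([[0.0, 0.0]] * 10 + [[100.0, 100.0]] * 10)
        res = kmeans(X, 2, seed=0)
        assert res.inertia == pytest.approx(0.0)
        assert len(np.unique(res.labels[:10])) == 1
        assert len(np.unique(res.labels[10:])) == 1

    def test_k_equals_distinct_points_zero_inertia(self):
        X = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        res = kmeans(X, 4, seed=0)
        assert res.inertia == pytest.approx(0.0)

    def test_matches_exhaustive_best_partition(self):
        """12 points in 3 blobs: k-means finds the global SSE optimum."""
        rng = np.random.default_rng(3)
        centers = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
        X = np.vstack([rng.normal(c, 1.0, size=(4, 2)) for c in centers])
        res = kmeans(X, 3, seed=0)

        def sse(assign):
            total = 0.0
            for c in range(3):
                pts = X[assign == c]
                if len(pts) == 0:
                    return np.inf
                total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        # exhaustive oracle over all 3-colorings (point 0 pinned to color 0)
        best = np.inf
        best_assign = None
        for rest in itertools.product(range(3), repeat=11):
            assign = np.array((0,) + rest)
            s = sse(assign)
            if s < best:
                best, best_assign = s, assign
        assert res.inertia == pytest.approx(best, rel=1e-9)
        # same partition up to label permutation
        for c in range(3):
            assert len(np.unique(res.labels[best_assign == c])) == 1

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((2, 2)), 3)


class TestCalinskiHarabasz:
    def test_perfect_separation_is_infinite(self):
        X = np.array([[0.0, 0]] * 5 + [[10.0, 10]] * 5)
        labels = np.array([1] * 5 + [2] * 5)
        assert calinski_harabasz(X, labels) == np.inf

    def test_identical_points_give_zero(self):
        X = np.zeros((8, 2))
        labels = np.array([1, 2] * 4)
        assert calinski_harabasz(X, labels) == 0.0

    def test_hand_computed_six_points(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [10, 10], [11, 10], [10, 11]])
        labels = np.array([1, 1, 1, 2, 2, 2])
        # within: each cluster has SSE sum = 2 * (2/3 + 2/3 ...) computed directly
        within = sum(
            ((X[labels == u] - X[labels == u].mean(0)) ** 2).sum() for u in (1, 2)
        )
        grand = X.mean(0)
        between = sum(
            3 * ((X[labels == u].mean(0) - grand) ** 2).sum() for u in (1, 2)
        )
        expected = (between / 1) / (within / 4)
        assert calinski_harabasz(X, labels) == pytest.approx(expected)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz_score(X, labels)
        )

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        labels = rng.integers(1, 4, size=30)
        perm = np.array([0, 3, 1, 2])  # relabel 1->3, 2->1, 3->2
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz(X, perm[labels])
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            calinski_harabasz(np.zeros((5, 2)), np.ones(5))


class TestSelectK:
    def test_three_populations_select_three(self, phantom_case):
        vfm = build_voxel_vectors(phantom_case)
        best_k, results = select_k(vfm, seed=0)
        assert best_k == 3
        assert set(results) == set(range(2, 11))

    def test_two_populations_select_two(self):
        from habikit.synthetic import PhantomSpec, Population, generate_phantom

        spec = PhantomSpec(
            populations=[
                Population(0.5, 150.0, 130.0, 10.0),
                Population(0.5, 30.0, 45.0, 10.0),
            ],
            seed=4,
        )
        case, _ = generate_phantom(spec)
        best_k, _ = select_k(build_voxel_vectors(case), seed=0)
        assert best_k == 2

    def test_single_cloud_still_returns_argmax(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        best_k, results = select_k(X, k_range=range(2, 6), seed=0)
        assert best_k in range(2, 6)

    def test_scale_invariance_of_partition(self, phantom_case):
        vfm = build_voxel_vectors(phantom_case)
        r1 = kmeans(vfm.matrix, 3, seed=5)
        r2 = kmeans(vfm.matrix * 3.0, 3, seed=5)
        # same partition up to label names
        for lbl in (1, 2, 3):
            assert len(np.unique(r2.labels[r1.labels == lbl])) == 1


class TestCohortSelection:
    def test_mean_ch_curve_recovers_three(self):
        from habikit.habitats import select_k_cohort
        from habikit.synthetic import default_phantom_spec, generate_phantom

        matrices = []
        for seed in range(3):
            case, _ = generate_phantom(default_phantom_spec(seed=40 + seed))
            matrices.append(build_voxel_vectors(case))
        best, log = select_k_cohort(matrices, k_range=range(2, 6), seed=0)
        assert best == 3
        assert log["per_case_best_k"] == [3, 3, 3]


class TestOrdering:
    def test_most_enhancing_becomes_sub1(self, phantom_case, phantom_truth):
        hmap, _ = compute_habitats(phantom_case, k=3, seed=0)
        vfm = build_voxel_vectors(phantom_case)
        sums = []
        for lbl in (1, 2, 3):
            sel = hmap.volume[tuple(np.array(np.nonzero(phantom_case.mask)))] == lbl
            sums.append(vfm.matrix[sel].sum(axis=1).mean())
        assert sums[0] >= sums[1] >= sums[2]
        # and matches the planted population ordering almost everywhere
        inside = phantom_case.mask > 0
        agree = (hmap.volume[inside] == phantom_truth.volume[inside]).mean()
        assert agree > 0.95

    def test_tie_break_by_arterial_mean(self):
        from habikit.habitats import ClusteringResult, VoxelFeatureMatrix

        # equal arterial+venous sums, different arterial means
        X = np.array([[50.0, 10.0]] * 3 + [[10.0, 50.0]] * 3)
        coords = tuple(np.array([[0, 0, i] for i in range(6)]).T)
        vfm = VoxelFeatureMatrix(X, coords, (1, 1, 6))
        res = ClusteringResult(
            k=2, labels=np.array([1] * 3 + [2] * 3),
            centroids=np.array([[50.0, 10], [10, 50]]), ch_score=1.0, inertia=0.0, seed=0,
        )
        hmap = order_subregions(res, vfm)
        assert np.all(hmap.volume[0, 0, :3] == 1)  # higher arterial mean -> sub1
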