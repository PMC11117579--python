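import numpy as np
import pytest

from _oracles import naive_centroids, naive_fcm, naive_objective, naive_opening
from conftest import make_phantom
from discmorph.errors import SegmentationError
from discmorph.fcm import (
    FcmConfig,
    fcm_fit,
    fcm_objective,
    init_membership,
    remove_interference,
    select_np_cluster,
    update_centroids,
    update_membership,
)
from discmorph.morphometry import dice_coefficient
from discmorph.preprocess import kmeans_crop, kmeans_intensity
from skimage.measure import label as cc_label
from skimage.morphology import disk


class TestInitMembership:
    def test_rows_sum_to_one(self):
        U = init_membership(50, 3, seed=0)
        assert np.allclose(U.sum(axis=1), 1.0, atol=1e-12)
        assert ((U >= 0) & (U <= 1)).all()

    def test_deterministic(self):
        assert np.array_equal(init_membership(20, 2, 5), init_membership(20, 2, 5))

    def test_too_few_clusters_or_objects_rejected(self):
        with pytest.raises(ValueError):
            init_membership(10, 1, 0)
        with pytest.raises(ValueError):
            init_membership(3, 3, 0)


class TestUpdateCentroids:
    def test_hard_membership_gives_cluster_means(self):
        X = np.array([0.1, 0.2, 0.8, 0.9])
        U = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        assert np.allclose(update_centroids(U, X, m=2.0), [0.15, 0.85])

    def test_uniform_membership_collapses_to_grand_mean(self):
        X = np.array([0.2, 0.8])
        U = np.full((2, 2), 0.5)
        assert np.allclose(update_centroids(U, X, m=2.0), [0.5, 0.5])

    def test_matches_double_loop_oracle(self, rng):
        X = rng.random(30)
        U = init_membership(30, 3, seed=1)
        assert np.allclose(
            update_centroids(U, X, m=2.0), naive_centroids(U, X, m=2.0), atol=1e-12
        )

    def test_empty_cluster_rejected(self):
        U = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(SegmentationError):
            update_centroids(U, np.array([0.1, 0.2, 0.3]), m=2.0)


class TestUpdateMembership:
    def test_equidistant_point_splits_evenly(self):
        U = update_membership(np.array([0.5]), np.array([0.4, 0.6]), m=2.0)
        assert np.allclose(U, [[0.5, 0.5]])

    def test_point_at_center_is_crisp(self):
        U = update_membership(np.array([0.4]), np.array([0.4, 0.6]), m=2.0)
        assert np.allclose(U, [[1.0, 0.0]])

    def test_hand_computed_ratio(self):
        # distances 0.1 and 0.4; squared ratio 16 -> memberships 16/17, 1/17
        U = update_membership(np.array([0.0]), np.array([0.1, 0.4]), m=2.0)
        assert np.allclose(U, [[16 / 17, 1 / 17]], atol=1e-12)


class TestObjective:
    def test_zero_when_points_sit_on_their_centers(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert fcm_objective(U, np.array([0.2, 0.7]), np.array([0.2, 0.7]), 2.0) == 0.0

    def test_zero_membership_masks_distance(self):
        U = np.array([[1.0, 0.0]])
        assert fcm_objective(U, np.array([0.5, 1.0]), np.array([0.5]), 2.0) == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        X = rng.random(20)
        U = init_membership(20, 3, seed=2)
        centers = rng.random(3)
        assert abs(
            fcm_objective(U, centers, X, 2.0) - naive_objective(U, centers, X, 2.0)
        ) < 1e-12


class TestFcmFit:
    def test_two_valued_data_separates_perfectly(self):
        X = np.array([0.2] * 25 + [0.8] * 25)
        part = fcm_fit(X, FcmConfig(c=2, seed=0))
        assert np.allclose(np.sort(part.centers), [0.2, 0.8], atol=1e-6)
        assert (part.U.max(axis=1) >= 0.99).all()

    def test_deterministic(self, rng):
        X = rng.random(60)
        a = fcm_fit(X, FcmConfig(c=3, seed=4))
        b = fcm_fit(X, FcmConfig(c=3, seed=4))
        assert np.array_equal(a.U, b.U) and np.array_equal(a.centers, b.centers)

    def test_objective_trace_non_increasing(self, rng):
        X = rng.random(100)
        part = fcm_fit(X, FcmConfig(c=3, seed=5))
        assert np.all(np.diff(part.objective_trace) <= 1e-12)

    def test_row_sums_hold_at_convergence(self, rng):
        X = rng.random(80)
        part = fcm_fit(X, FcmConfig(c=3, seed=6))
        assert np.allclose(part.U.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_independent_naive_solver(self, rng):
        X = rng.random(10)
        cfg = FcmConfig(c=2, seed=7)
        part = fcm_fit(X, cfg)
        U0 = init_membership(10, 2, seed=7)
        j_ref, trace_ref, _ = naive_fcm(X, 2, cfg.m, cfg.tol, cfg.max_iter, U0)
        assert abs(part.J - j_ref) < 1e-8
        assert np.allclose(part.objective_trace, trace_ref, atol=1e-8)

    def test_label_structure_invariant_to_point_order(self, rng):
        X = rng.random(40)
        perm = rng.permutation(40)
        cfg = FcmConfig(c=2, seed=8, tol=1e-12, max_iter=500)
        a = fcm_fit(X, cfg)
        b = fcm_fit(X[perm], cfg)
        # same data regardless of order: centroid sets must agree
        assert np.allclose(np.sort(a.centers), np.sort(b.centers), atol=1e-6)

    def test_hardened_partition_matches_kmeans_on_two_classes(self):
        X = np.array([0.1] * 20 + [0.9] * 30)
        part = fcm_fit(X, FcmConfig(c=2, seed=9))
        fcm_labels = np.argmax(part.U, axis=1)
        order = np.argsort(part.centers)
        fcm_sorted = np.searchsorted(part.centers[order], part.centers)[fcm_labels]
        _, km_labels, _ = kmeans_intensity(X, k=2, seed=9)
        assert np.array_equal(fcm_sorted, km_labels)


class TestSelectNpCluster:
    def test_exact_recovery_on_sharp_noise_free_phantom(self, noiseless_phantom):
        """Three exact intensity populations (zeroed background / AF / NP):
        the brightest of c=3 clusters is the nucleus, pixel for pixel."""
        ph = noiseless_phantom
        crop = kmeans_crop(ph.image, ph.ivd_contour_true, seed=0)
        part = fcm_fit(crop.image.pixels.ravel(), FcmConfig(c=3, seed=0))
        mask = select_np_cluster(part, np.ones(crop.image.shape, dtype=bool))
        r0, c0 = crop.origin
        h, w = crop.disc_mask.shape
        assert np.array_equal(mask & crop.disc_mask, ph.np_mask_true[r0 : r0 + h, c0 : c0 + w])

    def test_all_equal_centroids_select_cluster_zero(self):
        from discmorph.fcm import FuzzyPartition

        U = np.array([[0.5, 0.5], [0.5, 0.5]])
        part = FuzzyPartition(U, np.array([0.4, 0.4]), 0.0, 1, True, np.array([0.0]))
        disc = np.array([[True, True]])
        mask = select_np_cluster(part, disc)
        # tie on membership and on brightness: everything goes to cluster 0
        assert mask.all()

    def test_noisy_phantom_dice_over_085(self, noisy_phantom):
        ph = noisy_phantom
        crop = kmeans_crop(ph.image, ph.ivd_contour_true, seed=1)
        part = fcm_fit(crop.image.pixels.ravel(), FcmConfig(c=3, seed=1))
        sel = select_np_cluster(part, np.ones(crop.image.shape, dtype=bool))
        mask = remove_interference(sel & crop.disc_mask, 2)
        r0, c0 = crop.origin
        h, w = crop.disc_mask.shape
        truth = ph.np_mask_true[r0 : r0 + h, c0 : c0 + w]
        assert dice_coefficient(mask, truth) >= 0.85


class TestRemoveInterference:
    def test_specks_removed_blob_kept(self):
        mask = np.zeros((30, 30), bool)
        mask[5:20, 5:20] = True
        mask[25, 25] = True
        mask[2, 27] = True
        out = remove_interference(mask, radius=1)
        assert out[6:19, 6:19].all() and not out[25, 25] and not out[2, 27]

    def test_opening_is_idempotent(self, rng):
        from conftest import random_blob
        from skimage.morphology import opening

        blob = random_blob(rng)
        once = opening(blob, disk(2))
        assert np.array_equal(once, opening(once, disk(2)))

    def test_opening_matches_set_shifting_oracle(self, rng):
        from skimage.morphology import opening

        for _ in range(3):
            mask = rng.random((15, 15)) > 0.5
            assert np.array_equal(opening(mask, disk(1)), naive_opening(mask, 1))

    def test_empty_result_raises(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True  # single pixel dies under opening
        with pytest.raises(SegmentationError):
            remove_interference(mask, radius=2)
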