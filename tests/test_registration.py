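import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import SimilarityTransform as SkimageSimilarity

from exmquant import synthetic as syn
from exmquant.image_io import max_project
from exmquant.registration import (
    InsufficientKeypointsError,
    MatchSet,
    SimilarityTransform,
    demons_refine,
    detect_and_match_keypoints,
    find_best_z_projection,
    fit_similarity_ransac,
    refine_matches_subpixel,
    register_rounds,
)


class TestSimilarityTransform:
    def test_apply_then_invert_is_identity(self):
        t = SimilarityTransform(scale=4.2, rotation=0.7, translation=(3.0, -8.5))
        pts = np.random.default_rng(0).uniform(-50, 50, (20, 2))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_matrix_agrees_with_apply(self):
        t = SimilarityTransform(scale=2.0, rotation=-0.3, translation=(1.0, 2.0))
        pts = np.random.default_rng(1).uniform(0, 10, (5, 2))
        m = t.matrix()
        via_matrix = (m[:2, :2] @ pts.T).T + m[:2, 2]
        assert np.allclose(t.apply(pts), via_matrix)

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            SimilarityTransform(scale=0.0)


class TestKeypointMatching:
    def test_self_match_has_mostly_zero_displacement(self, blob_image):
        matches = detect_and_match_keypoints(blob_image, blob_image)
        disp = np.linalg.norm(matches.points_a - matches.points_b, axis=1)
        assert (disp < 1e-6).mean() >= 0.9

    def test_scaled_copy_matches_follow_known_transform(self):
        pre, post, truth = syn.gen_expansion_pair(
            scale=4.0, seed=11, pre_shape=(128, 128), n_objects=40, noise_sd=0.0
        )
        proj = max_project(post, 0, truth.content_z_window)
        matches = detect_and_match_keypoints(pre, proj)
        transform, filtered = fit_similarity_ransac(matches, seed=0)
        refined = refine_matches_subpixel(pre, proj, filtered, transform)
        inl = refined.inliers()
        err = np.linalg.norm(truth.transform.apply(inl.points_a) - inl.points_b, axis=1)
        assert np.median(err) <= 2.0

    def test_constant_image_raises(self):
        with pytest.raises(InsufficientKeypointsError, match="constant"):
            detect_and_match_keypoints(np.zeros((64, 64)), np.ones((64, 64)))


class TestSimilarityRansac:
    @pytest.fixture()
    def clean_correspondences(self):
        rng = np.random.default_rng(2)
        truth = SimilarityTransform(scale=3.5, rotation=0.4, translation=(10.0, -4.0))
        pts = rng.uniform(0, 150, (60, 2))
        return truth, MatchSet(pts, truth.apply(pts))

    def test_exact_recovery_matches_procrustes_oracle(self, clean_correspondences):
        truth, matches = clean_correspondences
        fitted, filtered = fit_similarity_ransac(matches, seed=0)
        assert fitted.scale == pytest.approx(truth.scale, abs=1e-6)
        assert fitted.rotation == pytest.approx(truth.rotation, abs=1e-6)
        assert np.allclose(fitted.translation, truth.translation, atol=1e-6)
        assert filtered.inlier_mask.all()
        # independent closed-form oracle (skimage total-least-squares estimate)
        oracle = SkimageSimilarity()
        oracle.estimate(matches.points_a[:, ::-1], matches.points_b[:, ::-1])
        assert fitted.scale == pytest.approx(oracle.scale, abs=1e-9)

    def test_robust_to_thirty_percent_outliers(self, clean_correspondences):
        truth, matches = clean_correspondences
        rng = np.random.default_rng(3)
        pb = matches.points_b.copy()
        bad = rng.choice(len(pb), 18, replace=False)
        pb[bad] = rng.uniform(0, 600, (18, 2))
        fitted, filtered = fit_similarity_ransac(MatchSet(matches.points_a, pb), seed=1)
        assert abs(fitted.scale - truth.scale) / truth.scale <= 1e-3
        assert not filtered.inlier_mask[bad].any()

    def test_identity_correspondences(self):
        pts = np.random.default_rng(4).uniform(0, 99, (30, 2))
        fitted, _ = fit_similarity_ransac(MatchSet(pts, pts), seed=0)
        assert fitted.scale == pytest.approx(1.0, abs=1e-9)
        assert fitted.rotation == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fitted.translation, (0, 0), atol=1e-9)

    def test_reproducible_for_fixed_seed_and_monotone_in_tol(self, clean_correspondences):
        truth, matches = clean_correspondences
        noisy = MatchSet(
            matches.points_a,
            matches.points_b + np.random.default_rng(5).normal(0, 1.2, matches.points_b.shape),
        )
        t1, f1 = fit_similarity_ransac(noisy, seed=9)
        t2, f2 = fit_similarity_ransac(noisy, seed=9)
        assert t1.scale == t2.scale and np.array_equal(f1.inlier_mask, f2.inlier_mask)
        counts = [
            fit_similarity_ransac(noisy, inlier_tol=tol, seed=9)[1].n_inliers
            for tol in (1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts)

    def test_rotation_equivariance_of_scale(self, clean_correspondences):
        _, matches = clean_correspondences
        rot = SimilarityTransform(rotation=0.9)
        rotated = MatchSet(rot.apply(matches.points_a), rot.apply(matches.points_b))
        s0, _ = fit_similarity_ransac(matches, seed=0)
        s1, _ = fit_similarity_ransac(rotated, seed=0)
        assert s1.scale == pytest.approx(s0.scale, rel=1e-12)

    def test_low_inlier_fraction_flags_low_confidence(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 100, (40, 2))
        pb = rng.uniform(0, 100, (40, 2))  # unrelated: only chance agreements
        pb[:4] = pts[:4]  # a small consistent subset
        with pytest.warns(UserWarning, match="low confidence"):
            fitted, _ = fit_similarity_ransac(MatchSet(pts, pb), inlier_tol=0.5, seed=0)
        assert fitted.low_confidence

    def test_too_few_matches_raise(self):
        with pytest.raises(InsufficientKeypointsError):
            fit_similarity_ransac(MatchSet(np.zeros((1, 2)), np.zeros((1, 2))))


class TestBestZProjection:
    def test_selected_window_overlaps_content_planes(self, expansion_pair_4x):
        pre, post, truth = expansion_pair_4x
        window, proj, matches, transform = find_best_z_projection(
            pre, post, window_lengths=range(3, 7), stride=2, seed=0
        )
        lo, hi = truth.content_z_window
        assert window[0] < hi and window[1] > lo  # overlaps the signal planes
        assert matches.n_inliers >= 4
        assert transform.scale == pytest.approx(4.0, rel=0.01)

    def test_single_plane_stack_reduces_to_direct_matching(self, blob_image):
        from exmquant.image_io import ImageStack

        stack = ImageStack(blob_image[None, None])
        window, proj, matches, _ = find_best_z_projection(
            blob_image, stack, window_lengths=[1], seed=0
        )
        assert window == (0, 1)
        assert np.array_equal(proj, blob_image)


class TestSubpixelRefinement:
    def test_refinement_tightens_residuals_on_pure_similarity(self, expansion_pair_4x):
        pre, post, truth = expansion_pair_4x
        proj = max_project(post, 0, truth.content_z_window)
        matches = detect_and_match_keypoints(pre, proj)
        transform, filtered = fit_similarity_ransac(matches, seed=0)
        refined = refine_matches_subpixel(pre, proj, filtered, transform)
        m = filtered.inlier_mask
        before = np.linalg.norm(transform.apply(filtered.points_a[m]) - filtered.points_b[m], axis=1)
        after = np.linalg.norm(transform.apply(refined.points_a[m]) - refined.points_b[m], axis=1)
        assert np.median(after) < np.median(before)


class TestDemons:
    def test_identity_pair_yields_negligible_field(self, blob_image):
        field = demons_refine(blob_image, blob_image, n_iter=20)
        assert field.magnitude().max() <= 1e-3

    def test_known_warp_recovered_within_one_pixel(self):
        rng = np.random.default_rng(0)
        fixed = syn.render_blobs((64, 64), *syn._blob_params(rng, 30, (64, 64), 5.0))
        warp = syn.smooth_warp_field((64, 64), 3.0, rng)
        yy, xx = np.mgrid[0:64, 0:64]
        moving = ndimage.map_coordinates(
            fixed, np.stack([yy + warp[0], xx + warp[1]]), order=1, mode="nearest"
        )
        field = demons_refine(moving, fixed, n_iter=60)
        mask = fixed > 0.1 * fixed.max()  # displacement is observable only on signal
        epe = np.sqrt(((field.field - (-warp)) ** 2).sum(axis=0))[mask]
        assert epe.mean() <= 1.0
        assert field.residuals == sorted(field.residuals, reverse=True)

    def test_residual_decreases_from_start_to_end(self, blob_image):
        moving = ndimage.shift(blob_image, (1.5, -1.0), order=1, mode="nearest")
        field = demons_refine(moving, blob_image, n_iter=30)
        assert field.residuals[-1] < field.residuals[0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            demons_refine(np.zeros((8, 8)), np.zeros((9, 9)))

    def test_3d_field_applies_to_other_channels(self):
        rng = np.random.default_rng(1)
        base = syn.render_blobs((48, 48), *syn._blob_params(rng, 20, (48, 48), 5.0))
        fixed = np.stack([base, base * 0.5])
        moving = np.stack(
            [ndimage.shift(p, (1.0, 1.0), order=1, mode="nearest") for p in fixed]
        )
        field = demons_refine(moving, fixed, n_iter=30)
        assert field.field.shape == (2, 2, 48, 48)
        warped = field.apply(moving)
        assert np.mean((warped - fixed) ** 2) < np.mean((moving - fixed) ** 2)


class TestRegisterRounds:
    def test_translation_mode_recovers_injected_offsets(self):
        rounds, truth = syn.gen_multiplexed_experiment(seed=3)
        _, transforms = register_rounds(rounds, mode="translation")
        for t, offset in zip(transforms, truth.offsets):
            assert np.allclose(t.translation, offset, atol=0.3)

    def test_registered_reference_channels_align(self):
        rounds, _ = syn.gen_multiplexed_experiment(seed=4)
        registered, _ = register_rounds(rounds, mode="translation")
        ref0 = registered[0].channel("DAPI")
        before = np.mean((rounds[1].channel("DAPI") - ref0) ** 2)
        after = np.mean((registered[1].channel("DAPI") - ref0) ** 2)
        assert after < 0.1 * before
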