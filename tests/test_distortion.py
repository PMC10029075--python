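import numpy as np
import pytest

from exmquant import synthetic as syn
from exmquant.distortion import (
    DistortionField,
    distortion_field,
    expansion_factor,
    normalize_to_biological_scale,
    rms_error_curve,
)
from exmquant.image_io import ImageStack
from exmquant.registration import MatchSet, SimilarityTransform


def matchset(points_a, points_b):
    return MatchSet(points_a, points_b, inlier_mask=np.ones(len(points_a), bool))


class TestDistortionField:
    def test_perfect_similarity_pair_has_zero_residuals(self):
        rng = np.random.default_rng(0)
        t = SimilarityTransform(scale=4.0, rotation=0.2, translation=(5, 5))
        pts = rng.uniform(0, 100, (40, 2))
        field = distortion_field(matchset(pts, t.apply(pts)), t, pixel_size_pre=0.1)
        assert np.linalg.norm(field.residual_vectors, axis=1).max() <= 1e-9

    def test_residuals_scale_linearly_with_pixel_size(self):
        rng = np.random.default_rng(1)
        t = SimilarityTransform(scale=4.0)
        pts = rng.uniform(0, 100, (30, 2))
        post = t.apply(pts) + rng.normal(0, 1.0, (30, 2))
        f1 = distortion_field(matchset(pts, post), t, pixel_size_pre=0.1)
        f2 = distortion_field(matchset(pts, post), t, pixel_size_pre=0.2)
        assert np.allclose(f2.residual_vectors, 2 * f1.residual_vectors)

    def test_generator_warp_bounds_residual_magnitude(self):
        _, _, truth = syn.gen_expansion_pair(scale=4.0, warp_amplitude=2.0, noise_sd=0, seed=3)
        pts = np.array([p for p, _ in truth.keypoint_truth])
        qts = np.array([q for _, q in truth.keypoint_truth])
        field = distortion_field(matchset(pts, qts), truth.transform, pixel_size_pre=0.1)
        # warp of <= 2 px in the post frame = 2/scale pre-px = 2/4*0.1 um
        assert np.linalg.norm(field.residual_vectors, axis=1).max() <= 2.0 / 4.0 * 0.1 + 1e-9

    def test_no_inliers_is_an_error(self):
        ms = MatchSet(np.zeros((3, 2)), np.zeros((3, 2)), inlier_mask=np.zeros(3, bool))
        with pytest.raises(ValueError, match="no inliers"):
            distortion_field(ms, SimilarityTransform(), 0.1)


class TestRMSCurve:
    def test_zero_residuals_give_zero_rms_everywhere(self):
        rng = np.random.default_rng(2)
        field = DistortionField(rng.uniform(0, 20, (50, 2)), np.zeros((50, 2)))
        curve = rms_error_curve(field, seed=0)
        assert np.all(curve.rms_error == 0)

    def test_iid_gaussian_residuals_plateau_at_twice_sigma(self):
        # E||v_i - v_j||^2 = 4 sigma^2 for 2D i.i.d. N(0, sigma^2 I) residuals,
        # verified against a brute-force pair enumeration on the same field
        rng = np.random.default_rng(3)
        sigma = 0.05
        anchors = rng.uniform(0, 40, (200, 2))
        resid = rng.normal(0, sigma, (200, 2))
        field = DistortionField(anchors, resid)
        curve = rms_error_curve(field, n_pairs_max=200_000, bin_width=5.0, seed=1)
        ii, jj = np.triu_indices(200, k=1)
        brute = np.sqrt(np.mean(np.sum((resid[ii] - resid[jj]) ** 2, axis=1)))
        well_sampled = curve.n_pairs >= 500
        assert brute == pytest.approx(2 * sigma, rel=0.05)
        assert np.allclose(curve.rms_error[well_sampled], brute, rtol=0.10)

    def test_seeded_sampling_is_reproducible(self):
        rng = np.random.default_rng(4)
        field = DistortionField(rng.uniform(0, 30, (500, 2)), rng.normal(0, 0.1, (500, 2)))
        c1 = rms_error_curve(field, n_pairs_max=1000, seed=7)
        c2 = rms_error_curve(field, n_pairs_max=1000, seed=7)
        assert np.array_equal(c1.rms_error, c2.rms_error)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            rms_error_curve(DistortionField(np.zeros((1, 2)), np.zeros((1, 2))))


class TestExpansionFactor:
    def test_keypoint_method_combines_scale_and_pixel_sizes(self):
        t = SimilarityTransform(scale=4.0)
        est = expansion_factor(
            method="keypoint", transform=t, pixel_size_pre=0.1, pixel_size_post=0.1
        )
        assert est.factor == pytest.approx(4.0)
        est2 = expansion_factor(
            method="keypoint", transform=t, pixel_size_pre=0.1, pixel_size_post=0.2
        )
        assert est2.factor == pytest.approx(8.0)

    def test_particle_area_recovers_generated_scale(self):
        pre, post, scale = syn.gen_particle_pair(scale=4.0, seed=0)
        est = expansion_factor(pre=pre, post=post, method="particle_area")
        assert est.factor == pytest.approx(4.0, rel=0.02)

    def test_identical_images_give_unit_factor(self, blob_image):
        est = expansion_factor(pre=blob_image, post=blob_image, method="particle_area")
        assert est.factor == pytest.approx(1.0)

    def test_length_and_tissue_methods(self):
        est = expansion_factor(
            method="length",
            lengths_pre=np.array([1.0, 1.2, 0.9]),
            lengths_post=np.array([3.6, 4.1, 3.2]),
        )
        assert est.factor == pytest.approx((3.6 + 4.1 + 3.2) / (1.0 + 1.2 + 0.9))
        # a cornea section expanding from 1.0 to 3.6 units in PBS
        est2 = expansion_factor(method="tissue_size", size_pre=1.0, size_post=3.6)
        assert est2.factor == pytest.approx(3.6)

    def test_blank_image_has_no_particles(self):
        with pytest.raises(ValueError, match="particle"):
            expansion_factor(
                pre=np.zeros((32, 32)), post=np.zeros((32, 32)),
                method="particle_area", threshold=0.5,
            )


class TestNormalization:
    def test_unit_factor_is_noop_on_pixel_sizes(self):
        stack = ImageStack(np.ones((1, 1, 4, 4)), pixel_size_xy=0.2, pixel_size_z=0.5)
        est = expansion_factor(method="tissue_size", size_pre=1.0, size_post=1.0)
        out = normalize_to_biological_scale(stack, est)
        assert out.pixel_size_xy == 0.2 and out.pixel_size_z == 0.5
        assert np.array_equal(out.data, stack.data)

    def test_measured_factor_rescales_pixel_size(self):
        # 0.108 um pixels at 5.79x expansion are 0.108/5.79 um biological
        stack = ImageStack(np.ones((1, 1, 4, 4)), pixel_size_xy=0.108, pixel_size_z=0.3)
        est = expansion_factor(method="tissue_size", size_pre=1.0, size_post=5.79)
        out = normalize_to_biological_scale(stack, est)
        assert out.pixel_size_xy == pytest.approx(0.108 / 5.79)
        assert out.expansion_factor == pytest.approx(5.79)

    def test_sequential_normalization_composes_multiplicatively(self):
        stack = ImageStack(np.ones((1, 1, 4, 4)), pixel_size_xy=1.0)
        ea = expansion_factor(method="tissue_size", size_pre=1.0, size_post=2.0)
        eb = expansion_factor(method="tissue_size", size_pre=1.0, size_post=3.0)
        twice = normalize_to_biological_scale(normalize_to_biological_scale(stack, ea), eb)
        once = normalize_to_biological_scale(
            stack, expansion_factor(method="tissue_size", size_pre=1.0, size_post=6.0)
        )
        assert twice.pixel_size_xy == pytest.approx(once.pixel_size_xy)
        assert twice.expansion_factor == pytest.approx(once.expansion_factor)
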