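"""Seeded end-to-end benchmarks of every pipeline stage against ground truth.

Each function simulates study-like conditions with the :mod:`exmquant.synthetic`
generators, runs the corresponding pipeline stage, and returns the measured
recovery errors. They are shared by the validation test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, stats

from exmquant import synthetic as syn
from exmquant.colocalization import (
    ColocMatrix,
    binarize_and_label,
    coloc_index,
    delta_matrix_anova,
)
from exmquant.distortion import (
    analyze_expansion_pair,
    distortion_field,
    expansion_factor,
    percent_distortion,
    rms_error_curve,
)
from exmquant.flunmix import RoundSeries, find_alpha_opt, unmix_series
from exmquant.image_io import Movie, max_project
from exmquant.registration import (
    MatchSet,
    SimilarityTransform,
    demons_refine,
    fit_similarity_lstsq,
    fit_similarity_ransac,
    register_rounds,
)
from exmquant.sofi import estimate_spot_sigma, sofi_xc2

__all__ = [
    "alpha_recovery_errors",
    "expansion_factor_errors",
    "distortion_identity_rms",
    "distortion_percent_recovery",
    "ransac_recovery",
    "sofi_recovery",
    "coloc_exactness",
    "demons_recovery",
    "end_to_end_multiplexed",
]


def alpha_recovery_errors(
    alphas=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    n_seeds: int = 5,
    shape=(256, 256),
    seed: int = 0,
) -> np.ndarray:
    """|alpha_hat - alpha_true| for every (alpha, seed) trial."""
    errors = []
    for a in alphas:
        for k in range(n_seeds):
            rounds, _ = syn.gen_round_series(
                n_rounds=2, alpha_per_round=(float(a),), shape=shape, seed=seed * 1000 + k * 17 + int(a * 100)
            )
            fit = find_alpha_opt(
                rounds[0].channel("marker")[0], rounds[1].channel("marker")[0]
            )
            errors.append(abs(fit.alpha_opt - a))
    return np.array(errors)


def expansion_factor_errors(scales=(2, 4, 6, 8), seed: int = 0) -> dict[str, np.ndarray]:
    """Relative errors of keypoint and particle-area expansion estimates."""
    kp, pa = [], []
    for s in scales:
        pre, post, truth = syn.gen_expansion_pair(
            scale=float(s), seed=seed * 100 + s, pre_shape=(128, 128), n_objects=40
        )
        proj = max_project(post, 0, truth.content_z_window)
        res = analyze_expansion_pair(pre, proj, seed=seed)
        kp.append(abs(res["expansion"].factor - s) / s)

        pre_p, post_p, _ = syn.gen_particle_pair(scale=float(s), seed=seed * 100 + s)
        est = expansion_factor(pre=pre_p, post=post_p, method="particle_area")
        pa.append(abs(est.factor - s) / s)
    return {"keypoint": np.array(kp), "particle_area": np.array(pa)}


def distortion_identity_rms(seed: int = 0) -> float:
    """Max RMS error (um) across bins for a noiseless identical pre/post pair."""
    pre, post, truth = syn.gen_expansion_pair(
        scale=1.0, warp_amplitude=0.0, noise_sd=0.0, seed=seed, pre_shape=(192, 192)
    )
    proj = max_project(post, 0, truth.content_z_window)
    res = analyze_expansion_pair(pre, proj, seed=seed)
    return float(res["curve"].rms_error.max())


def _truth_percent_distortion(truth, anchors_pre, pixel_size_pre=0.1, seed=0) -> float:
    """Warp-derived percent distortion evaluated at given pre-frame anchors.

    The exact generator warp supplies the true post position of every anchor;
    the same similarity-fit + residual-field + RMS-curve computation as the
    pipeline then yields the truth value at identical spatial sampling.
    """
    pts = np.asarray(anchors_pre, dtype=float)
    qts = truth.true_post_position(pts)
    fit = fit_similarity_lstsq(pts, qts)
    ms = MatchSet(pts, qts, inlier_mask=np.ones(len(pts), bool))
    curve = rms_error_curve(distortion_field(ms, fit, pixel_size_pre), seed=seed)
    return percent_distortion(curve)


def distortion_percent_recovery(
    n_seeds: int = 10, warp_amplitude: float = 3.0, seed: int = 0
) -> dict[str, float]:
    """Mean recovered vs warp-derived percent distortion over seeded fixtures."""
    rec, tru = [], []
    for k in range(n_seeds):
        pre, post, truth = syn.gen_expansion_pair(
            scale=4.0,
            warp_amplitude=warp_amplitude,
            seed=seed * 1000 + k,
            pre_shape=(192, 192),
            n_objects=80,
        )
        proj = max_project(post, 0, truth.content_z_window)
        res = analyze_expansion_pair(pre, proj, seed=seed)
        rec.append(res["percent_distortion"])
        anchors = res["matches"].inliers().points_a
        tru.append(_truth_percent_distortion(truth, anchors, seed=seed))
    return {"recovered": float(np.mean(rec)), "truth": float(np.mean(tru))}


def ransac_recovery(seed: int = 0) -> dict[str, float]:
    """Similarity recovery on clean and 30%-outlier correspondences."""
    rng = np.random.default_rng(seed)
    truth = SimilarityTransform(scale=4.0, rotation=0.3, translation=(11.0, -6.0))
    pts = rng.uniform(0, 200, (80, 2))
    clean = MatchSet(pts, truth.apply(pts))
    fit_clean, _ = fit_similarity_ransac(clean, seed=seed)
    clean_err = max(
        abs(fit_clean.scale - truth.scale),
        abs(fit_clean.rotation - truth.rotation),
        float(np.abs(np.array(fit_clean.translation) - truth.translation).max()),
    )
    corrupted = truth.apply(pts).copy()
    bad = rng.choice(80, 24, replace=False)
    corrupted[bad] = rng.uniform(0, 900, (24, 2))
    fit_out, _ = fit_similarity_ransac(MatchSet(pts, corrupted), seed=seed)
    return {
        "clean_max_error": float(clean_err),
        "outlier_scale_rel_error": float(abs(fit_out.scale - truth.scale) / truth.scale),
    }


def sofi_recovery(seed: int = 0) -> dict[str, float]:
    """Constant-movie null, FWHM narrowing and quadratic intensity scaling."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        const = sofi_xc2(Movie(np.full((60, 16, 16), 5.0))).xc2_image
    truth = syn.EmitterTruth(
        positions=[[24.0, 24.0]], p_on=0.4, p_off=0.5, psf_sigma=2.0, photon_rate=2000
    )
    movie, _ = syn.gen_blinking_movie(
        truth, n_frames=300, background=0.0, seed=seed, shape=(48, 48), poisson=False
    )
    res = sofi_xc2(movie)
    sigma_mean = estimate_spot_sigma(movie.frames.mean(axis=0))
    sigma_xc2 = estimate_spot_sigma(res.xc2_image) / 2
    scaled = sofi_xc2(Movie(movie.frames * 3.0)).xc2_image
    scaling_dev = float(
        np.max(np.abs(scaled - 9.0 * res.xc2_image)) / max(res.xc2_image.max() * 9.0, 1e-12)
    )
    return {
        "constant_movie_max": float(const.max()),
        "fwhm_ratio": float(sigma_xc2 / sigma_mean),
        "scaling_rel_dev": scaling_dev,
    }


def coloc_exactness(seed: int = 0, n_masks: int = 100) -> dict[str, float]:
    """Bit-exactness of coloc_index, connectivity and ANOVA against oracles."""
    from scipy import ndimage as ndi

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    conn_mismatch = 0
    structure = np.ones((3, 3, 3), bool)
    for _ in range(n_masks):
        a = rng.random((16, 16, 16)) < 0.15
        b = rng.random((16, 16, 16)) < 0.15
        la, na = ndi.label(a, structure=structure)
        lb, nb = ndi.label(b, structure=structure)
        from exmquant.colocalization import LabelVolume

        lva = LabelVolume(la, na, np.bincount(la.ravel())[1:])
        lvb = LabelVolume(lb, nb, np.bincount(lb.ravel())[1:])
        pa, pb = coloc_index(lva, lvb)
        overlap = int(np.logical_and(a, b).sum())  # brute-force voxel count
        brute_a = 100.0 * overlap / a.sum() if a.sum() else 0.0
        brute_b = 100.0 * overlap / b.sum() if b.sum() else 0.0
        max_diff = max(max_diff, abs(pa - brute_a), abs(pb - brute_b))
        # connectivity oracle: count components by repeated binary dilation growth
        n_oracle = _flood_count(a)
        if na != n_oracle:
            conn_mismatch += 1

    mask_a, mask_b, _ = syn.gen_label_volumes((32, 64, 64), (1000, 500), 0.5, seed=seed)
    la, na = ndi.label(mask_a, structure=structure)
    lb, nb = ndi.label(mask_b, structure=structure)
    from exmquant.colocalization import LabelVolume

    constructed = coloc_index(
        LabelVolume(la, na, np.bincount(la.ravel())[1:]),
        LabelVolume(lb, nb, np.bincount(lb.ravel())[1:]),
    )

    # two-group ANOVA vs the closed-form F CDF
    x = rng.normal(40, 5, 8)
    y = rng.normal(55, 5, 9)
    g1 = [ColocMatrix(np.array([[100.0, v], [v, 100.0]]), ["a", "b"]) for v in x]
    g2 = [ColocMatrix(np.array([[100.0, v], [v, 100.0]]), ["a", "b"]) for v in y]
    res = delta_matrix_anova(g1, g2)
    grand = np.concatenate([x, y]).mean()
    ssb = len(x) * (x.mean() - grand) ** 2 + len(y) * (y.mean() - grand) ** 2
    ssw = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
    f_stat = ssb / (ssw / (len(x) + len(y) - 2))
    p_closed = float(stats.f.sf(f_stat, 1, len(x) + len(y) - 2))
    return {
        "index_max_abs_diff": max_diff,
        "connectivity_mismatches": float(conn_mismatch),
        "constructed_pct_in_a": constructed[0],
        "constructed_pct_in_b": constructed[1],
        "anova_p_abs_diff": abs(res.p_values[0, 1] - p_closed),
    }


def _flood_count(mask: np.ndarray) -> int:
    """Component count by explicit 26-neighbourhood flood fill."""
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        n += 1
        stack = [start]
        labels[start] = n
        while stack:
            z, y, x = stack.pop()
            for dz in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        nz, ny, nx = z + dz, y + dy, x + dx
                        if (
                            (dz or dy or dx)
                            and 0 <= nz < mask.shape[0]
                            and 0 <= ny < mask.shape[1]
                            and 0 <= nx < mask.shape[2]
                            and mask[nz, ny, nx]
                            and not labels[nz, ny, nx]
                        ):
                            labels[nz, ny, nx] = n
                            stack.append((nz, ny, nx))
    return n


def demons_recovery(seed: int = 0, warp_amplitude: float = 3.0) -> dict[str, float]:
    """Endpoint error of the recovered field against a known smooth warp."""
    rng = np.random.default_rng(seed)
    fixed = syn.render_blobs((64, 64), *syn._blob_params(rng, 30, (64, 64), 5.0))
    warp = syn.smooth_warp_field((64, 64), warp_amplitude, rng)
    yy, xx = np.mgrid[0:64, 0:64]
    moving = ndimage.map_coordinates(
        fixed, np.stack([yy + warp[0], xx + warp[1]]), order=1, mode="nearest"
    )
    field = demons_refine(moving, fixed, n_iter=60)
    mask = fixed > 0.1 * fixed.max()
    epe = np.sqrt(((field.field - (-warp)) ** 2).sum(axis=0))[mask]
    monotone = all(b <= a + 1e-12 for a, b in zip(field.residuals, field.residuals[1:]))
    return {"mean_endpoint_error": float(epe.mean()), "residual_monotone": float(monotone)}


def end_to_end_multiplexed(seed: int = 0) -> dict[str, float]:
    """Register -> unmix -> colocalize a 3-round 4-channel series vs truth."""
    rounds, truth = syn.gen_multiplexed_experiment(seed=seed)
    registered, _ = register_rounds(rounds, mode="translation")
    result = unmix_series(RoundSeries(registered))
    labeled = {}
    n_rounds = len(rounds)
    for r in range(n_rounds):
        for c in range(1, rounds[0].n_channels):
            labeled[f"r{r}c{c}"] = binarize_and_label(result.true_images[f"marker{c}"][r])
    names = truth.marker_names
    mat = np.zeros((len(names), len(names)))
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            mat[i, j] = coloc_index(labeled[ni], labeled[nj])[0]
    err = np.abs(mat - truth.coloc_matrix)
    return {
        "max_abs_error_pp": float(err.max()),
        "mean_abs_error_pp": float(err.mean()),
        "n_cells": float(err.size),
    }
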