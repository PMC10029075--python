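"""Distortion fields, RMS measurement-error curves and expansion factors.

After the best similarity alignment of a pre/post-expansion image pair, the
per-keypoint residual vectors form the distortion vector field: everything the
isotropic expansion model cannot explain. Differencing the residual vectors of
random point pairs turns the field into distance-measurement errors, and the
RMS of those errors as a function of measurement length is the standard ExM
fidelity curve. The linear expansion factor itself can be estimated four ways
(keypoint transform scale, particle-area ratio, paired length ratio, gross
tissue-size ratio), and is used to normalize post-expansion images back to
biological scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from exmquant.image_io import ImageStack
from exmquant.registration import MatchSet, SimilarityTransform

__all__ = [
    "DistortionField",
    "RMSCurve",
    "ExpansionEstimate",
    "distortion_field",
    "rms_error_curve",
    "percent_distortion",
    "expansion_factor",
    "normalize_to_biological_scale",
]


@dataclass
class DistortionField:
    """Post-alignment residual vectors anchored at pre-image positions.

    Both anchors and residuals are in biological micrometres (pre-expansion
    physical scale), so curves from different expansion factors compare
    directly.
    """

    anchor_points: np.ndarray  # (n, 2) in µm, pre-expansion frame
    residual_vectors: np.ndarray  # (n, 2) in µm

    def __post_init__(self) -> None:
        self.anchor_points = np.atleast_2d(np.asarray(self.anchor_points, dtype=float))
        self.residual_vectors = np.atleast_2d(np.asarray(self.residual_vectors, dtype=float))
        if self.anchor_points.shape != self.residual_vectors.shape:
            raise ValueError("anchors and residuals must have matching shapes")
        if not np.all(np.isfinite(self.residual_vectors)):
            raise ValueError("residual vectors must be finite")

    def __len__(self) -> int:
        return len(self.anchor_points)


@dataclass
class RMSCurve:
    """RMS distance-measurement error vs measurement length."""

    length_bins: np.ndarray  # bin centres, µm
    rms_error: np.ndarray  # µm
    sem: np.ndarray  # µm
    n_pairs: np.ndarray  # samples per bin


@dataclass
class ExpansionEstimate:
    """Linear expansion factor and how it was obtained."""

    factor: float
    method: str  # keypoint | particle_area | length | tissue_size
    n: int = 1
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("expansion factor must be positive")


def distortion_field(
    inliers: MatchSet,
    transform: SimilarityTransform,
    pixel_size_pre: float,
) -> DistortionField:
    """Residual displacement per inlier match, on the biological scale.

    residual = (transform applied to the pre point) - matched post point,
    divided by the transform scale (back to pre-expansion pixels) and
    converted to micrometres with ``pixel_size_pre``.
    """
    m = inliers.inlier_mask
    if m is None:
        m = np.ones(len(inliers), dtype=bool)
    if not m.any():
        raise ValueError("match set has no inliers; cannot build a distortion field")
    pre = inliers.points_a[m]
    post = inliers.points_b[m]
    resid_px_post = transform.apply(pre) - post
    resid_um = resid_px_post / transform.scale * pixel_size_pre
    anchors_um = pre * pixel_size_pre
    return DistortionField(anchor_points=anchors_um, residual_vectors=resid_um)


def rms_error_curve(
    fields: DistortionField | list[DistortionField],
    n_pairs_max: int = 100_000,
    bin_width: float = 1.0,
    seed: int = 0,
) -> RMSCurve:
    """RMS distance-measurement error as a function of measurement length.

    For random anchor pairs (i, j), the error of measuring their distance is
    ||v_i - v_j|| (difference of the residual vectors) and the measurement
    length is the pre-image anchor distance. Errors are binned by length
    (``bin_width`` µm); each bin reports RMS, standard error of the mean RMS,
    and the pair count. When several fields of view are given, each FOV is
    sampled and curves are averaged per bin across FOVs (SEM across FOVs).
    """
    if isinstance(fields, DistortionField):
        fields = [fields]
    rng = np.random.default_rng(seed)
    per_fov: list[tuple[np.ndarray, np.ndarray]] = []
    max_len = 0.0
    for f in fields:
        n = len(f)
        if n < 2:
            raise ValueError("need at least 2 anchor points")
        budget = n_pairs_max // len(fields)
        n_all = n * (n - 1) // 2
        if n_all <= budget:
            ii, jj = np.triu_indices(n, k=1)
        else:
            ii = rng.integers(0, n, budget)
            jj = rng.integers(0, n, budget)
            keep = ii != jj
            ii, jj = ii[keep], jj[keep]
        lengths = np.linalg.norm(f.anchor_points[ii] - f.anchor_points[jj], axis=1)
        errors = np.linalg.norm(f.residual_vectors[ii] - f.residual_vectors[jj], axis=1)
        per_fov.append((lengths, errors))
        max_len = max(max_len, lengths.max())

    edges = np.arange(0.0, max_len + bin_width, bin_width)
    centres = edges[:-1] + bin_width / 2
    n_bins = len(centres)
    rms_fov = np.full((len(per_fov), n_bins), np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for k, (lengths, errors) in enumerate(per_fov):
        idx = np.clip(np.digitize(lengths, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                rms_fov[k, b] = np.sqrt(np.mean(errors[sel] ** 2))
                counts[b] += int(sel.sum())
    valid = ~np.all(np.isnan(rms_fov), axis=0)
    sub = rms_fov[:, valid]
    rms = np.nanmean(sub, axis=0)
    n_fov = np.sum(~np.isnan(sub), axis=0)
    sd = np.where(n_fov > 1, np.nanstd(np.where(np.isnan(sub), np.nan, sub), axis=0, ddof=0), 0.0)
    sem = np.where(n_fov > 1, sd / np.sqrt(np.maximum(n_fov, 1)), 0.0)
    return RMSCurve(
        length_bins=centres[valid],
        rms_error=rms,
        sem=sem,
        n_pairs=counts[valid],
    )


def percent_distortion(curve: RMSCurve, min_pairs: int = 50) -> float:
    """Scalar distortion summary: rms(L)/L at the curve's plateau.

    The plateau is taken as the largest well-populated length bin (at least
    ``min_pairs`` sampled pairs). Reported as a percentage of the measurement
    length. The definition is recorded here because a 'distortion %' scalar
    is convention-dependent; this one is a curve-derived upper summary.
    """
    ok = curve.n_pairs >= min_pairs
    if not ok.any():
        ok = curve.n_pairs > 0
    idx = np.where(ok)[0][-1]
    L = curve.length_bins[idx]
    return float(100.0 * curve.rms_error[idx] / L) if L > 0 else 0.0


def _particle_areas(
    img: np.ndarray, threshold: float | None, min_size: int, rel_min: float = 0.1
) -> np.ndarray:
    thr = threshold_otsu(img) if threshold is None else threshold
    labels, n = ndimage.label(img > thr)
    if n == 0:
        raise ValueError("no particles detected above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    sizes = sizes[sizes >= min_size]
    if sizes.size == 0:
        raise ValueError(f"no particles of at least {min_size} px detected")
    # noise satellites split off particle rims are tiny next to real particles:
    # drop anything below rel_min x the median area (FIJI-style size gating)
    sizes = sizes[sizes >= rel_min * np.median(sizes)]
    return sizes


def expansion_factor(
    pre=None,
    post=None,
    method: str = "keypoint",
    transform: SimilarityTransform | None = None,
    pixel_size_pre: float = 1.0,
    pixel_size_post: float = 1.0,
    threshold: float | None = None,
    min_particle_size: int = 5,
    lengths_pre: np.ndarray | None = None,
    lengths_post: np.ndarray | None = None,
    size_pre: float | None = None,
    size_post: float | None = None,
) -> ExpansionEstimate:
    """Linear expansion factor by one of four methods.

    - ``keypoint``: transform scale x (post/pre pixel size ratio), from the
      similarity fit of matched keypoints;
    - ``particle_area``: threshold + binarize both images, sqrt of the mean
      particle-area ratio in physical units (suspension samples);
    - ``length``: ratio of mean paired length samples (cell widths);
    - ``tissue_size``: gross size ratio of the specimen (whole tissues).
    """
    if method == "keypoint":
        if transform is None:
            raise ValueError("keypoint method needs a fitted SimilarityTransform")
        factor = transform.scale * (pixel_size_post / pixel_size_pre)
        return ExpansionEstimate(factor=factor, method=method)
    if method == "particle_area":
        if pre is None or post is None:
            raise ValueError("particle_area method needs pre and post images")
        a_pre = _particle_areas(np.asarray(pre, dtype=float), threshold, min_particle_size)
        a_post = _particle_areas(np.asarray(post, dtype=float), threshold, min_particle_size)
        ratio = (a_post.mean() * pixel_size_post**2) / (a_pre.mean() * pixel_size_pre**2)
        if ratio <= 0:
            raise ValueError("non-positive particle-area ratio")
        return ExpansionEstimate(
            factor=float(np.sqrt(ratio)), method=method, n=len(a_post), sd=0.0
        )
    if method == "length":
        if lengths_pre is None or lengths_post is None:
            raise ValueError("length method needs paired length samples")
        lp = np.asarray(lengths_pre, dtype=float)
        lq = np.asarray(lengths_post, dtype=float)
        ratios = lq / lp if lp.shape == lq.shape else None
        factor = float(lq.mean() / lp.mean())
        sd = float(np.std(ratios)) if ratios is not None and ratios.size > 1 else 0.0
        return ExpansionEstimate(factor=factor, method=method, n=lp.size, sd=sd)
    if method == "tissue_size":
        if size_pre is None or size_post is None or size_pre <= 0:
            raise ValueError("tissue_size method needs positive pre and post sizes")
        return ExpansionEstimate(factor=float(size_post / size_pre), method=method)
    raise ValueError(f"unknown expansion-factor method {method!r}")


def analyze_expansion_pair(
    pre: np.ndarray,
    post_projection: np.ndarray,
    pixel_size_pre: float = 0.1,
    pixel_size_post: float | None = None,
    inlier_tol: float = 4.0,
    seed: int = 0,
    refine: bool = True,
):
    """Full pre/post distortion analysis of one field of view.

    SIFT matching, similarity RANSAC, optional subpixel refinement of the
    inlier matches by local phase correlation (and a least-squares refit on
    the refined points), then the distortion field, RMS curve, plateau
    percent-distortion scalar and keypoint expansion-factor estimate.
    Returns a dict with keys ``transform``, ``matches``, ``field``, ``curve``,
    ``percent_distortion``, ``expansion``.
    """
    from exmquant.registration import (
        detect_and_match_keypoints,
        fit_similarity_lstsq,
        fit_similarity_ransac,
        refine_matches_subpixel,
    )

    matches = detect_and_match_keypoints(pre, post_projection)
    transform, filtered = fit_similarity_ransac(matches, inlier_tol=inlier_tol, seed=seed)
    if refine:
        filtered = refine_matches_subpixel(pre, post_projection, filtered, transform)
        transform = fit_similarity_lstsq(
            filtered.points_a[filtered.inlier_mask], filtered.points_b[filtered.inlier_mask]
        )
    field = distortion_field(filtered, transform, pixel_size_pre)
    curve = rms_error_curve(field, seed=seed)
    est = expansion_factor(
        method="keypoint",
        transform=transform,
        pixel_size_pre=pixel_size_pre,
        pixel_size_post=pixel_size_post if pixel_size_post is not None else pixel_size_pre,
    )
    return {
        "transform": transform,
        "matches": filtered,
        "field": field,
        "curve": curve,
        "percent_distortion": percent_distortion(curve),
        "expansion": est,
    }


def normalize_to_biological_scale(stack: ImageStack, estimate: ExpansionEstimate) -> ImageStack:
    """Rescale pixel metadata by the expansion factor; intensities untouched.

    Dividing the physical pixel sizes by the linear expansion factor expresses
    post-expansion images in pre-expansion ('biological') units, which also
    absorbs the small sample-to-sample variability of the expansion itself.
    """
    prior = stack.expansion_factor or 1.0
    return ImageStack(
        data=stack.data.copy(),
        pixel_size_xy=stack.pixel_size_xy / estimate.factor,
        pixel_size_z=stack.pixel_size_z / estimate.factor,
        channel_names=list(stack.channel_names),
        expansion_factor=prior * estimate.factor,
        dtype_on_disk=stack.dtype_on_disk,
    )
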