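"""Keypoint, similarity and deformable registration.

Pre/post-expansion pairing follows the classic ExM validation recipe: SIFT
keypoints matched between the pre-expansion image and candidate post-expansion
z-projections, filtered by RANSAC under a geometric model restricted to
rotation + translation + uniform scaling (the physical model of an isotropic
hydrogel expansion). Multi-round stacks are first aligned rigidly on the
nuclear reference channel and then refined with diffeomorphic demons; the
demons displacement field computed on the reference channel is applied to the
other channels of the same round.

Coordinates are (y, x), 0-based, pixel centres at integer positions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.feature import SIFT, match_descriptors
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "MatchSet",
    "SimilarityTransform",
    "DisplacementField",
    "InsufficientKeypointsError",
    "FitFailureError",
    "detect_and_match_keypoints",
    "fit_similarity_lstsq",
    "fit_similarity_ransac",
    "find_best_z_projection",
    "demons_refine",
    "register_rounds",
]


class InsufficientKeypointsError(RuntimeError):
    """Raised when too few keypoint matches exist to fit a transform."""


class FitFailureError(RuntimeError):
    """Raised when consensus fitting finds no inliers at all."""


@dataclass
class MatchSet:
    """Paired keypoint coordinates between two images."""

    points_a: np.ndarray  # (n, 2) (y, x) in image a
    points_b: np.ndarray  # (n, 2) (y, x) in image b
    scores: np.ndarray | None = None  # descriptor distance per match
    inlier_mask: np.ndarray | None = None  # set by consensus fitting

    def __post_init__(self) -> None:
        self.points_a = np.atleast_2d(np.asarray(self.points_a, dtype=float))
        self.points_b = np.atleast_2d(np.asarray(self.points_b, dtype=float))
        if self.points_a.shape != self.points_b.shape:
            raise ValueError("points_a and points_b must have equal shapes")

    def __len__(self) -> int:
        return len(self.points_a)

    @property
    def n_inliers(self) -> int:
        return 0 if self.inlier_mask is None else int(self.inlier_mask.sum())

    def inliers(self) -> "MatchSet":
        m = self.inlier_mask if self.inlier_mask is not None else np.ones(len(self), bool)
        return MatchSet(
            self.points_a[m],
            self.points_b[m],
            None if self.scores is None else self.scores[m],
            np.ones(int(m.sum()), bool),
        )


@dataclass
class SimilarityTransform:
    """Rotation + translation + uniform scale, acting on (y, x) points.

    ``apply`` maps a point p to ``s * R(rotation) @ p + t``. Internally the
    2D similarity is handled as complex multiplication z -> a z + t with
    z = x + iy, a = s e^{i rotation}.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)  # (ty, tx)
    low_confidence: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def _complex(self) -> tuple[complex, complex]:
        a = self.scale * np.exp(1j * self.rotation)
        t = self.translation[1] + 1j * self.translation[0]
        return a, t

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        a, t = self._complex()
        z = points[:, 1] + 1j * points[:, 0]
        w = a * z + t
        return np.stack([w.imag, w.real], axis=1)

    def inverse(self) -> "SimilarityTransform":
        a, t = self._complex()
        ai = 1.0 / a
        ti = -ai * t
        return SimilarityTransform(
            scale=abs(ai), rotation=float(np.angle(ai)), translation=(ti.imag, ti.real)
        )

    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (y, x, 1) column vectors."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.eye(3)
        # in (y, x): y' = s*(cos*y + sin*x) + ty ; x' = s*(-sin*y + cos*x) + tx
        m[0, :2] = self.scale * np.array([c, s])
        m[1, :2] = self.scale * np.array([-s, c])
        m[:2, 2] = self.translation
        return m


@dataclass
class DisplacementField:
    """Dense displacement u with warped_moving(x) = moving(x + u(x)).

    ``field`` has components (dy, dx) first: shape (2, H, W) for 2D and
    (2, Z, H, W) for plane-matched 3D fields.
    """

    field: np.ndarray
    residuals: list[float] = field(default_factory=list)
    diverged: bool = False

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.field**2).sum(axis=0))

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Warp an image (same shape the field was computed on)."""
        if self.field.ndim == 3:  # (2, H, W)
            yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
            coords = np.stack([yy + self.field[0], xx + self.field[1]])
            return ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        out = np.empty_like(image, dtype=float)
        for z in range(image.shape[0]):
            yy, xx = np.mgrid[0 : image.shape[1], 0 : image.shape[2]]
            coords = np.stack([yy + self.field[0, z], xx + self.field[1, z]])
            out[z] = ndimage.map_coordinates(image[z], coords, order=1, mode="nearest")
        return out


# ---------------------------------------------------------------------------
# keypoints


def _sift_features(img: np.ndarray):
    det = SIFT()
    det.detect_and_extract(np.ascontiguousarray(img, dtype=float))
    return det.keypoints.astype(float), det.descriptors


def detect_and_match_keypoints(
    img_a: np.ndarray,
    img_b: np.ndarray,
    max_ratio: float = 0.8,
    min_matches: int = 4,
) -> MatchSet:
    """SIFT keypoints in both images, matched with a ratio test.

    Raises :class:`InsufficientKeypointsError` when fewer than ``min_matches``
    matches survive; the caller must then supply a transform by hand (there is
    no interactive alignment fallback).
    """
    for name, img in (("img_a", img_a), ("img_b", img_b)):
        if np.ptp(img) == 0:
            raise InsufficientKeypointsError(f"{name} is constant; no keypoints can be detected")
    try:
        kp_a, desc_a = _sift_features(img_a)
        kp_b, desc_b = _sift_features(img_b)
    except RuntimeError as exc:  # skimage raises when no keypoints survive
        raise InsufficientKeypointsError(str(exc)) from exc
    return _match_features(kp_a, desc_a, kp_b, desc_b, max_ratio, min_matches)


def _match_features(kp_a, desc_a, kp_b, desc_b, max_ratio=0.8, min_matches=4) -> MatchSet:
    pairs = match_descriptors(desc_a, desc_b, max_ratio=max_ratio, cross_check=True)
    if len(pairs) < min_matches:
        raise InsufficientKeypointsError(
            f"only {len(pairs)} keypoint matches found (need >= {min_matches}); "
            "supply a transform explicitly"
        )
    dists = np.linalg.norm(
        desc_a[pairs[:, 0]].astype(float) - desc_b[pairs[:, 1]].astype(float), axis=1
    )
    return MatchSet(kp_a[pairs[:, 0]], kp_b[pairs[:, 1]], scores=dists)


# ---------------------------------------------------------------------------
# similarity fitting


def fit_similarity_lstsq(
    points_a: np.ndarray, points_b: np.ndarray, lock_scale: bool = False
) -> SimilarityTransform:
    """Closed-form least-squares similarity mapping points_a -> points_b.

    The complex-regression form of the 2D Procrustes problem: with
    z_k = x_k + i y_k, minimise sum |a z_k + t - w_k|^2, giving
    a = cov(z, w) / var(z). ``lock_scale`` normalises |a| to 1 (rigid fit).
    """
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    if len(pa) < 2:
        raise ValueError("need at least 2 point pairs")
    z = pa[:, 1] + 1j * pa[:, 0]
    w = pb[:, 1] + 1j * pb[:, 0]
    zc, wc = z - z.mean(), w - w.mean()
    denom = np.vdot(zc, zc).real
    if denom == 0:
        raise FitFailureError("degenerate point configuration (all source points equal)")
    a = np.vdot(zc, wc) / denom  # vdot conjugates the first argument
    if lock_scale:
        if a == 0:
            raise FitFailureError("degenerate rigid fit")
        a = a / abs(a)
    if abs(a) == 0:
        raise FitFailureError("degenerate similarity fit (zero scale)")
    t = w.mean() - a * z.mean()
    return SimilarityTransform(
        scale=float(abs(a)), rotation=float(np.angle(a)), translation=(t.imag, t.real)
    )


def fit_similarity_ransac(
    matches: MatchSet,
    inlier_tol: float = 3.0,
    max_iter: int = 2000,
    seed: int = 0,
    lock_scale: bool = False,
) -> tuple[SimilarityTransform, MatchSet]:
    """Consensus similarity fit over noisy keypoint matches.

    Two point pairs determine a similarity exactly; ``max_iter`` random
    2-pair hypotheses are scored by inlier count at ``inlier_tol`` pixels in
    the target frame, and the winner is refit by least squares on its inliers
    (twice, re-selecting inliers in between). Deterministic given ``seed``.

    An inlier fraction below 25% flags the result ``low_confidence``; zero
    inliers raise :class:`FitFailureError`.
    """
    n = len(matches)
    if n < 2:
        raise InsufficientKeypointsError("need at least 2 matches for a similarity fit")
    rng = np.random.default_rng(seed)
    pa, pb = matches.points_a, matches.points_b

    best_count, best_err, best_mask = 0, np.inf, None
    for _ in range(max_iter):
        i, j = rng.choice(n, size=2, replace=False)
        if np.allclose(pa[i], pa[j]):
            continue
        try:
            cand = fit_similarity_lstsq(pa[[i, j]], pb[[i, j]], lock_scale=lock_scale)
        except FitFailureError:
            continue
        resid = np.linalg.norm(cand.apply(pa) - pb, axis=1)
        mask = resid <= inlier_tol
        count = int(mask.sum())
        err = float(resid[mask].sum()) if count else np.inf
        if count > best_count or (count == best_count and err < best_err):
            best_count, best_err, best_mask = count, err, mask
        if best_count == n:
            break
    if best_count < 2:
        raise FitFailureError("no consensus: fewer than 2 inliers under the similarity model")

    mask = best_mask
    transform = None
    for _ in range(2):  # refit, re-select inliers, refit
        transform = fit_similarity_lstsq(pa[mask], pb[mask], lock_scale=lock_scale)
        resid = np.linalg.norm(transform.apply(pa) - pb, axis=1)
        mask = resid <= inlier_tol
        if not mask.any():
            raise FitFailureError("no inliers after least-squares refit")
    transform.seed = seed
    if mask.sum() / n < 0.25:
        transform.low_confidence = True
        warnings.warn(
            f"similarity consensus kept only {mask.sum()}/{n} matches; low confidence",
            stacklevel=2,
        )
    out = MatchSet(pa, pb, matches.scores, mask)
    return transform, out


def refine_matches_subpixel(
    img_a: np.ndarray,
    img_b: np.ndarray,
    matches: MatchSet,
    transform: SimilarityTransform,
    patch: int = 12,
    upsample_factor: int = 20,
) -> MatchSet:
    """Refine matched positions by local phase correlation after alignment.

    Keypoint detectors localise to a fraction of a pixel at best, which caps
    the precision of distortion measurements. Here ``img_b`` is resampled into
    ``img_a``'s frame through ``transform``; around every inlier anchor a
    (2*patch+1)^2 patch of both images is phase-correlated (subpixel,
    1/``upsample_factor`` px) and the b-point is re-derived from the measured
    local offset. Matches whose patch leaves the frame keep their original
    coordinates.
    """
    m = transform.matrix()
    warped = ndimage.affine_transform(
        np.asarray(img_b, dtype=float), m[:2, :2], offset=m[:2, 2],
        output_shape=img_a.shape, order=1, mode="constant",
    )
    new_b = matches.points_b.copy()
    keep = matches.inlier_mask if matches.inlier_mask is not None else np.ones(len(matches), bool)
    for i in np.flatnonzero(keep):
        cy, cx = matches.points_a[i]
        y0, x0 = int(round(cy)) - patch, int(round(cx)) - patch
        y1, x1 = y0 + 2 * patch + 1, x0 + 2 * patch + 1
        if y0 < 0 or x0 < 0 or y1 > img_a.shape[0] or x1 > img_a.shape[1]:
            continue
        pa_patch = img_a[y0:y1, x0:x1]
        wb_patch = warped[y0:y1, x0:x1]
        if np.ptp(pa_patch) == 0 or np.ptp(wb_patch) == 0:
            continue
        shift, _, _ = phase_cross_correlation(
            pa_patch, wb_patch, upsample_factor=upsample_factor, normalization=None
        )
        # feature at a-position p sits at p - shift in the warped image, i.e.
        # its true b-frame position is transform(p - shift)
        new_b[i] = transform.apply((matches.points_a[i] - shift)[None])[0]
    return MatchSet(matches.points_a, new_b, matches.scores, matches.inlier_mask)


# ---------------------------------------------------------------------------
# best-z pairing


def find_best_z_projection(
    pre_img: np.ndarray,
    post_stack,
    window_lengths=range(5, 31),
    channel: int | str = 0,
    inlier_tol: float = 3.0,
    seed: int = 0,
    stride: int = 1,
):
    """Find the post-expansion z-projection that best matches a pre-expansion plane.

    All contiguous z-windows with lengths in ``window_lengths`` are
    max-projected, SIFT-matched against ``pre_img`` and similarity-filtered;
    the window with the most inliers wins. Returns
    ``(z_window, projection, matchset, transform)``.
    """
    from exmquant.image_io import max_project

    vol = post_stack.channel(channel)
    depth = vol.shape[0]
    lengths = [w for w in window_lengths if 1 <= w <= depth]
    if not lengths:
        raise ValueError(f"no window length in {window_lengths!r} fits depth {depth}")
    kp_pre, desc_pre = _sift_features(pre_img)

    best = None
    for w in lengths:
        for start in range(0, depth - w + 1, stride):
            proj = max_project(post_stack, channel, (start, start + w))
            if np.ptp(proj) == 0:
                continue
            try:
                kp, desc = _sift_features(proj)
                matches = _match_features(kp_pre, desc_pre, kp, desc)
                transform, filtered = fit_similarity_ransac(
                    matches, inlier_tol=inlier_tol, seed=seed
                )
            except (InsufficientKeypointsError, FitFailureError, RuntimeError):
                continue
            if best is None or filtered.n_inliers > best[2].n_inliers:
                best = ((start, start + w), proj, filtered, transform)
    if best is None:
        raise InsufficientKeypointsError(
            "no z-window produced >= 4 similarity inliers against the pre-expansion image"
        )
    return best


# ---------------------------------------------------------------------------
# demons


def _demons_2d(
    moving: np.ndarray,
    fixed: np.ndarray,
    n_iter: int,
    smoothing_sigma: float,
    chunk: int,
) -> tuple[np.ndarray, list[float], bool]:
    fixed_img = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float32))
    moving_img = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float32))
    filt = sitk.DiffeomorphicDemonsRegistrationFilter()
    filt.SetSmoothDisplacementField(True)
    filt.SetStandardDeviations(smoothing_sigma)

    field_img = None
    residuals: list[float] = []
    diverged = False
    rising = 0
    done = 0
    while done < n_iter:
        step = min(chunk, n_iter - done)
        filt.SetNumberOfIterations(step)
        if field_img is None:
            field_img = filt.Execute(fixed_img, moving_img)
        else:
            field_img = filt.Execute(fixed_img, moving_img, field_img)
        done += step
        arr = sitk.GetArrayFromImage(field_img)  # (H, W, 2) with (dx, dy) vectors
        u = np.stack([arr[..., 1], arr[..., 0]])
        warped = DisplacementField(u).apply(moving)
        resid = float(np.mean((warped - fixed) ** 2))
        if residuals and resid > residuals[-1]:
            rising += 1
            if rising >= 3:
                diverged = True
                residuals.append(resid)
                warnings.warn(
                    "demons residual increased 3 evaluations running; stopping early",
                    stacklevel=3,
                )
                break
        else:
            rising = 0
        residuals.append(resid)
    arr = sitk.GetArrayFromImage(field_img)
    return np.stack([arr[..., 1], arr[..., 0]]), residuals, diverged


def demons_refine(
    moving: np.ndarray,
    fixed: np.ndarray,
    n_iter: int = 60,
    smoothing_sigma: float = 1.5,
    chunk: int = 10,
) -> DisplacementField:
    """Diffeomorphic demons refinement of an already rigidly aligned pair.

    Intensity-difference-driven demons updates, Gaussian-regularised
    (``smoothing_sigma`` px) and composed diffeomorphically, run in chunks of
    ``chunk`` iterations so a rising mean-squared residual can trigger an
    early stop with a warning. 3D inputs are registered plane-by-plane (each
    z-plane is a quasi-independent optical section); the returned field can be
    applied to any other channel of the same round.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share a shape")
    if moving.ndim == 2:
        u, residuals, diverged = _demons_2d(moving, fixed, n_iter, smoothing_sigma, chunk)
        return DisplacementField(u, residuals, diverged)
    if moving.ndim != 3:
        raise ValueError("demons_refine expects 2D or 3D arrays")
    fields, residuals, diverged = [], [], False
    for z in range(moving.shape[0]):
        u, res, div = _demons_2d(moving[z], fixed[z], n_iter, smoothing_sigma, chunk)
        fields.append(u)
        residuals.append(res[-1] if res else 0.0)
        diverged = diverged or div
    return DisplacementField(np.stack(fields, axis=1), residuals, diverged)


# ---------------------------------------------------------------------------
# multi-round rigid alignment


def _apply_similarity_to_image(image: np.ndarray, transform: SimilarityTransform) -> np.ndarray:
    """Resample ``image`` so that out(x) = image(T(x)) (T in fixed-frame coords)."""
    m = transform.matrix()
    return ndimage.affine_transform(
        image, m[:2, :2], offset=m[:2, 2], order=1, mode="constant"
    )


def register_rounds(
    rounds: list,
    ref_channel: str | int = "DAPI",
    mode: str = "auto",
    seed: int = 0,
    refine_demons: bool = False,
    demons_iter: int = 40,
):
    """Rigidly align each imaging round to the first on the reference channel.

    ``mode='keypoint'`` uses SIFT + rigid (scale-locked) RANSAC on the
    reference-channel max projections; ``mode='translation'`` uses subpixel
    phase correlation; ``'auto'`` tries keypoints and falls back to phase
    correlation. Optionally refines with per-plane demons on the reference
    channel and applies the field to every channel.

    Returns ``(registered_rounds, transforms)``.
    """
    from exmquant.image_io import ImageStack, max_project

    ref = rounds[0]
    ref_proj = max_project(ref, ref_channel, (0, ref.n_planes))
    registered = [rounds[0]]
    transforms: list[SimilarityTransform] = [SimilarityTransform()]
    for rnd in rounds[1:]:
        mov_proj = max_project(rnd, ref_channel, (0, rnd.n_planes))
        transform = None
        if mode in ("keypoint", "auto"):
            try:
                matches = detect_and_match_keypoints(ref_proj, mov_proj)
                transform, _ = fit_similarity_ransac(matches, seed=seed, lock_scale=True)
            except (InsufficientKeypointsError, FitFailureError):
                if mode == "keypoint":
                    raise
        if transform is None:
            # amplitude-weighted correlation: phase whitening is unstable on
            # smooth low-texture projections like nuclear stains; iterate to
            # remove the interpolation bias of the first correction
            total = np.zeros(2)
            work = mov_proj
            for _ in range(3):
                shift, _, _ = phase_cross_correlation(
                    ref_proj, work, upsample_factor=20, normalization=None
                )
                total += shift
                if np.abs(shift).max() < 0.05:
                    break
                work = ndimage.shift(mov_proj, total, order=1, mode="nearest")
            # reference(x) ~ moving(x - shift): T maps fixed coords to moving coords
            transform = SimilarityTransform(translation=(-total[0], -total[1]))
        data = np.stack(
            [
                np.stack(
                    [_apply_similarity_to_image(plane, transform) for plane in rnd.data[c]]
                )
                for c in range(rnd.n_channels)
            ]
        )
        if refine_demons:
            ref_i = rounds[0].channel(ref_channel)
            mov_i = data[rnd.channel_names.index(ref_channel) if isinstance(ref_channel, str) else ref_channel]
            fld = demons_refine(mov_i.squeeze(), ref_i.squeeze(), n_iter=demons_iter)
            data = np.stack([fld.apply(data[c].squeeze()).reshape(data[c].shape) for c in range(len(data))])
        registered.append(
            ImageStack(
                np.clip(data, 0, None),
                pixel_size_xy=rnd.pixel_size_xy,
                pixel_size_z=rnd.pixel_size_z,
                channel_names=rnd.channel_names,
            )
        )
        transforms.append(transform)
    return registered, transforms
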