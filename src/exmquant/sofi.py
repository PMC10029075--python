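"""Second-order cumulant SOFI reconstruction.

Super-resolution optical fluctuation imaging exploits the stochastic blinking
of emitters: the second-order zero-lag cumulant of a pixel's time series,
XC2(a) = < dF_a(t) dF_a(t) > with dF = F - <F>_t, retains only correlated
fluctuations. Because the cumulant of a Gaussian PSF is the PSF squared, the
effective PSF width shrinks by sqrt(2). Cross-cumulants between neighbouring
pixels, < dF_a dF_b >, carry the signal of a *virtual* pixel halfway between
a and b, which doubles the pixel grid.

The pipeline mirrors a standard fluctuation-imaging chain: drift + intensity
correction of the raw movie, per-plane XC2 on the doubled grid, then
Richardson-Lucy deconvolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.restoration import richardson_lucy

from exmquant.image_io import Movie

__all__ = [
    "SofiResult",
    "correct_drift_intensity",
    "sofi_xc2",
    "lucy_richardson",
    "gaussian_psf",
    "reconstruct",
    "estimate_spot_sigma",
]


@dataclass
class SofiResult:
    """XC2 reconstruction on the 2x denser virtual grid."""

    xc2_image: np.ndarray  # (2H-1, 2W-1) cumulant image, absolute-value convention
    deconvolved: np.ndarray | None = None
    n_frames_used: int = 0
    drift_track: np.ndarray | None = None  # (t, 2) (dy, dx) per frame


def correct_drift_intensity(
    movie: Movie,
    upsample_factor: int = 10,
    max_drift_fraction: float = 0.25,
    n_passes: int = 3,
    block_size: int = 5,
) -> tuple[Movie, np.ndarray]:
    """Drift- and intensity-correct a movie before cumulant analysis.

    Single blinking frames share only part of their content with the temporal
    mean, so drift is estimated on means of ``block_size``-frame blocks (where
    the blinking averages out) by subpixel phase correlation
    (1/``upsample_factor`` px precision) and linearly interpolated to every
    frame. Because drift smears the reference mean itself, estimation and
    correction are iterated ``n_passes`` times against the re-sharpened mean.
    Each frame is then divided by its spatial mean and rescaled to the global
    mean, removing slow illumination/bleaching trends. Borders invalidated by
    the maximum drift are cropped. Returns the corrected movie and the
    per-frame (dy, dx) drift track (the shift applied to each frame).
    """
    frames = movie.frames
    n_frames = movie.n_frames
    drift = np.zeros((n_frames, 2))
    corrected = frames.copy()
    block = max(1, min(block_size, n_frames // 2))
    starts = list(range(0, n_frames, block))
    centers = np.array([min(s + block, n_frames) / 2 + s / 2 - 0.5 for s in starts])
    if np.ptp(frames.mean(axis=0)) > 0:
        # pass 0: sequential block-to-block correlation handles drifts too
        # large for a direct comparison with the (smeared) global mean
        if len(starts) > 1:
            block_means = [frames[s : s + block].mean(axis=0) for s in starts]
            seq = np.zeros((len(starts), 2))
            for b in range(1, len(starts)):
                shift, _, _ = phase_cross_correlation(
                    block_means[b - 1], block_means[b],
                    upsample_factor=upsample_factor, normalization=None,
                )
                seq[b] = seq[b - 1] + shift
            seq -= seq.mean(axis=0)  # reference the correction to the mean position
            cand_drift = np.stack(
                [np.interp(np.arange(n_frames), centers, seq[:, k]) for k in (0, 1)], axis=1
            )
            candidate = np.stack(
                [
                    ndimage.shift(frames[t], cand_drift[t], order=1, mode="nearest")
                    if np.any(cand_drift[t])
                    else frames[t]
                    for t in range(n_frames)
                ]
            )
            # real drift sharpens the temporal mean; spurious alignments of
            # blinking content do not — keep the correction only if it helps
            if candidate.mean(axis=0).var() > frames.mean(axis=0).var():
                drift = cand_drift
                corrected = candidate
        for _ in range(n_passes):
            mean_img = corrected.mean(axis=0)
            block_shift = np.zeros((len(starts), 2))
            for b, s in enumerate(starts):
                block_mean = corrected[s : s + block].mean(axis=0)
                shift, _, _ = phase_cross_correlation(
                    mean_img, block_mean, upsample_factor=upsample_factor,
                    normalization=None,
                )
                block_shift[b] = shift
            delta = np.stack(
                [np.interp(np.arange(n_frames), centers, block_shift[:, k]) for k in (0, 1)],
                axis=1,
            )
            drift += delta
            for t in range(n_frames):
                corrected[t] = (
                    ndimage.shift(frames[t], drift[t], order=1, mode="nearest")
                    if np.any(drift[t])
                    else frames[t]
                )
            if np.abs(delta).max() < 0.05:
                break
    span = float((drift.max(axis=0) - drift.min(axis=0)).max()) if len(drift) else 0.0
    if span > max_drift_fraction * min(frames.shape[1:]):
        raise RuntimeError(
            f"estimated drift span {span:.1f} px exceeds {max_drift_fraction:.0%} of the frame"
        )
    global_mean = frames.mean()
    spatial_means = corrected.mean(axis=(1, 2))
    factors = np.divide(
        global_mean, spatial_means, out=np.ones_like(spatial_means), where=spatial_means > 0
    )
    adjust = np.abs(factors - 1.0) > 1e-12  # leave already-uniform frames bit-exact
    corrected[adjust] *= factors[adjust, None, None]

    crop = int(np.ceil(np.abs(drift).max())) if len(drift) else 0
    if crop:
        corrected = corrected[:, crop:-crop or None, crop:-crop or None]
    out = Movie(corrected, movie.frame_interval, movie.pixel_size_xy)
    return out, drift


def sofi_xc2(movie: Movie) -> SofiResult:
    """Zero-lag second-order (cross-)cumulant image on the doubled pixel grid.

    Physical pixels carry the auto-cumulant (temporal variance); virtual
    pixels between two physical neighbours (horizontal, vertical, diagonal)
    carry the zero-lag cross-cumulant of their flanking pixels. The output
    grid is (2H-1, 2W-1): exactly doubled minus the border row/column that has
    no flanking pair. Values follow the absolute-value convention (>= 0).

    A temporally constant movie yields an all-zero image with a warning.
    """
    frames = movie.frames
    delta = frames - frames.mean(axis=0)
    if np.ptp(delta) == 0:
        warnings.warn("movie is temporally constant; XC2 is identically zero", stacklevel=2)
    h, w = frames.shape[1:]
    out = np.zeros((2 * h - 1, 2 * w - 1))
    out[::2, ::2] = (delta * delta).mean(axis=0)  # auto-cumulant
    out[::2, 1::2] = (delta[:, :, :-1] * delta[:, :, 1:]).mean(axis=0)  # horizontal
    out[1::2, ::2] = (delta[:, :-1, :] * delta[:, 1:, :]).mean(axis=0)  # vertical
    # diagonal virtual pixels: average the two crossing diagonal cumulants
    d1 = (delta[:, :-1, :-1] * delta[:, 1:, 1:]).mean(axis=0)
    d2 = (delta[:, :-1, 1:] * delta[:, 1:, :-1]).mean(axis=0)
    out[1::2, 1::2] = 0.5 * (d1 + d2)
    return SofiResult(xc2_image=np.abs(out), n_frames_used=movie.n_frames)


def gaussian_psf(sigma: float, radius: int | None = None) -> np.ndarray:
    """Normalized 2D Gaussian kernel (sums to 1)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = radius or int(np.ceil(4 * sigma))
    y, x = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(y**2 + x**2) / (2 * sigma**2))
    return k / k.sum()


def lucy_richardson(image: np.ndarray, psf: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Richardson-Lucy deconvolution (multiplicative update, non-negative).

    ``psf`` must be normalized to unit sum; ``n_iter`` >= 1. The default of 10
    iterations sharpens without strong noise amplification on cumulant images.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    psf = np.asarray(psf, dtype=float)
    total = psf.sum()
    if not np.isfinite(total) or total <= 0 or abs(total - 1.0) > 1e-6:
        raise ValueError("psf must be normalizable and normalized to sum 1")
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("Richardson-Lucy requires a non-negative image")
    return richardson_lucy(image, psf, num_iter=n_iter, clip=False, filter_epsilon=1e-12)


def reconstruct(
    movie: Movie,
    psf_sigma: float | None = None,
    n_iter: int = 10,
    correct: bool = True,
) -> SofiResult:
    """Full chain: drift/intensity correction, XC2, Richardson-Lucy.

    ``psf_sigma`` is the width of the *XC2-domain* PSF in virtual pixels; when
    omitted it is estimated from the second moment of the brightest isolated
    spot of the XC2 image.
    """
    drift = None
    if correct:
        movie, drift = correct_drift_intensity(movie)
    result = sofi_xc2(movie)
    result.drift_track = drift
    img = result.xc2_image
    if img.max() > 0:
        sigma = psf_sigma if psf_sigma is not None else estimate_spot_sigma(img)
        result.deconvolved = lucy_richardson(img, gaussian_psf(sigma), n_iter=n_iter)
    return result


def estimate_spot_sigma(image: np.ndarray, window: int = 8) -> float:
    """Gaussian width (px) of the brightest spot, by intensity-weighted moments."""
    cy, cx = np.unravel_index(np.argmax(image), image.shape)
    y0, y1 = max(0, cy - window), min(image.shape[0], cy + window + 1)
    x0, x1 = max(0, cx - window), min(image.shape[1], cx + window + 1)
    patch = image[y0:y1, x0:x1].astype(float)
    patch = patch - patch.min()
    if patch.sum() == 0:
        return 1.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    w = patch / patch.sum()
    my, mx = (w * yy).sum(), (w * xx).sum()
    var = (w * ((yy - my) ** 2 + (xx - mx) ** 2)).sum() / 2
    return float(max(np.sqrt(var), 0.5))
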