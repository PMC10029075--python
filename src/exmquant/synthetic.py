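"""Seeded synthetic data with known ground truth for every pipeline stage.

Real expansion-microscopy inputs are large microscope stacks; these generators
emulate their geometry and statistics at test-friendly sizes while recording
the exact ground truth (transforms, warp displacements, carry-over
coefficients, emitter states, voxel overlaps) needed to score every downstream
estimate without re-simulation.

All generators are deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from exmquant.image_io import ImageStack, Movie
from exmquant.registration import SimilarityTransform

__all__ = [
    "ExpansionPairTruth",
    "RoundSeriesTruth",
    "ColocTruth",
    "EmitterTruth",
    "MultiplexTruth",
    "gen_expansion_pair",
    "gen_round_series",
    "gen_label_volumes",
    "gen_blinking_movie",
    "gen_multiplexed_experiment",
    "render_blobs",
    "smooth_warp_field",
]


# ---------------------------------------------------------------------------
# truth records


@dataclass
class ExpansionPairTruth:
    """Ground truth for a simulated pre/post expansion image pair."""

    transform: SimilarityTransform  # maps pre (y,x) -> post (y,x), warp excluded
    warp_amplitude: float  # max |displacement| of the non-rigid component, px
    keypoint_truth: list[tuple[np.ndarray, np.ndarray]]  # (pre_yx, post_yx) pairs
    content_z_window: tuple[int, int]  # planes of the post stack holding signal
    warp_displacements: np.ndarray  # (n, 2) warp displacement at each keypoint
    warp_field: np.ndarray | None = None  # (2, H, W) post-frame displacement field

    def true_post_position(self, pre_points: np.ndarray) -> np.ndarray:
        """Exact post-frame position of arbitrary pre-frame points."""
        rigid = self.transform.apply(pre_points)
        if self.warp_field is None:
            return rigid
        return rigid + _sample_warp(self.warp_field, rigid)

    @property
    def scale(self) -> float:
        return self.transform.scale

    @property
    def rotation(self) -> float:
        return self.transform.rotation


@dataclass
class RoundSeriesTruth:
    """Ground truth for a cumulative-staining round series."""

    alpha_per_round: np.ndarray  # carry-over coefficient per transition
    true_images: list[ImageStack]  # per-round true signals, pre-offset/noise
    registration_offsets: np.ndarray  # (n_rounds, 2) rigid (dy, dx) per round


@dataclass
class ColocTruth:
    """Directional overlap fractions for a constructed mask pair."""

    overlap_voxels: int
    vol_a: int
    vol_b: int

    @property
    def fraction_in_a(self) -> float:
        return self.overlap_voxels / self.vol_a if self.vol_a else 0.0

    @property
    def fraction_in_b(self) -> float:
        return self.overlap_voxels / self.vol_b if self.vol_b else 0.0


@dataclass
class EmitterTruth:
    """Two-state blinking emitters imaged through a Gaussian PSF."""

    positions: np.ndarray  # (n, 2) subpixel (y, x)
    p_on: float = 0.3  # off -> on probability per frame
    p_off: float = 0.5  # on -> off probability per frame
    psf_sigma: float = 1.5  # px
    photon_rate: float = 400.0  # photons/frame while on

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if not (0.0 < self.p_on <= 1.0 and 0.0 <= self.p_off < 1.0):
            raise ValueError("switching probabilities must lie in (0, 1)")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


@dataclass
class MultiplexTruth:
    """Ground truth for a full multi-round multiplexed experiment."""

    marker_names: list[str]  # e.g. r0c1 ... one per (round, channel)
    marker_masks: dict[str, np.ndarray]  # binary (z, y, x) per marker
    alpha: np.ndarray  # (n_channels - 1, n_rounds - 1) per-channel carry-over
    offsets: np.ndarray  # (n_rounds, 2) in-plane rigid offset per round
    coloc_matrix: np.ndarray  # (n_markers, n_markers) true overlap percentages


# ---------------------------------------------------------------------------
# primitives


def render_blobs(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigmas: np.ndarray,
    amplitudes: np.ndarray,
    angles: np.ndarray | None = None,
) -> np.ndarray:
    """Render anisotropic Gaussian blobs at subpixel centers.

    ``sigmas`` is (n, 2) per-axis widths in the blob frame; ``angles`` rotates
    each blob. Slight anisotropy plus varying peaks gives keypoint detectors
    real texture to lock onto.
    """
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    if angles is None:
        angles = np.zeros(len(centers))
    for (cy, cx), (sy, sx), amp, th in zip(centers, sigmas, amplitudes, angles):
        r = int(np.ceil(4 * max(sy, sx))) + 1
        y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        dy = yy[y0:y1, x0:x1] - cy
        dx = xx[y0:y1, x0:x1] - cx
        c, s = np.cos(th), np.sin(th)
        u = c * dy + s * dx
        v = -s * dy + c * dx
        img[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((u / sy) ** 2 + (v / sx) ** 2))
    return img


def render_discs(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    amplitudes: np.ndarray,
    edge: float = 1.0,
) -> np.ndarray:
    """Render plateau-topped discs with a soft (sigmoid) rim of width ``edge``.

    Cell-like particles: unlike Gaussian blobs their thresholded area is
    insensitive to the exact threshold, which is what makes area-based
    expansion-factor estimation well-posed.
    """
    from scipy.special import expit

    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (cy, cx), r0, amp in zip(centers, radii, amplitudes):
        r = int(np.ceil(r0 + 6 * edge)) + 1
        y0, y1 = max(0, int(cy) - r), min(shape[0], int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(shape[1], int(cx) + r + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        rr = np.hypot(yy[y0:y1, x0:x1] - cy, xx[y0:y1, x0:x1] - cx)
        img[y0:y1, x0:x1] += amp * expit((r0 - rr) / edge)
    return img


def gen_particle_pair(
    n_particles: int = 30,
    scale: float = 4.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    pre_shape: tuple[int, int] = (128, 128),
    radius_range: tuple[float, float] = (3.0, 5.0),
    amp_range: tuple[float, float] = (160.0, 255.0),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pre/post pair of a particle suspension for area-based expansion estimation.

    Separated plateau-topped particles (cell bodies) are rendered, then
    re-rendered at ``scale`` times the size with Poisson + Gaussian noise on
    the post image. Returns ``(pre, post, scale)``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    margin = radius_range[1] + 6.0
    centers, _, _, _ = _blob_params(
        rng, n_particles, pre_shape, margin, min_separation=2 * radius_range[1] + 6
    )
    radii = rng.uniform(*radius_range, n_particles)
    amps = rng.uniform(*amp_range, n_particles)
    pre = render_discs(pre_shape, centers, radii, amps)
    post_shape = (int(round(scale * pre_shape[0])), int(round(scale * pre_shape[1])))
    c_pre = (np.array(pre_shape, dtype=float) - 1) / 2
    c_post = (np.array(post_shape, dtype=float) - 1) / 2
    post_centers = scale * (centers - c_pre) + c_post
    # the rim scales with the expansion: the post image is self-similar to pre
    post = render_discs(post_shape, post_centers, radii * scale, amps, edge=scale)
    if noise_sd > 0:
        post = np.clip(
            rng.poisson(np.clip(post, 0, None)).astype(float)
            + rng.normal(0, noise_sd, post.shape),
            0,
            None,
        )
    return pre, post, float(scale)


def smooth_warp_field(
    shape: tuple[int, int],
    amplitude: float,
    rng: np.random.Generator,
    grid: int = 5,
) -> np.ndarray:
    """Band-limited zero-mean displacement field, (2, H, W), max norm = amplitude.

    A coarse ``grid`` x ``grid`` random displacement lattice is upsampled with
    cubic splines, recentred to zero mean, and rescaled so that the maximum
    displacement magnitude equals ``amplitude`` pixels — distortion as a single
    controllable scalar.
    """
    if amplitude < 0:
        raise ValueError("warp amplitude must be >= 0")
    field = np.zeros((2,) + tuple(shape), dtype=float)
    if amplitude == 0:
        return field
    coarse = rng.standard_normal((2, grid, grid))
    for k in range(2):
        field[k] = ndimage.zoom(coarse[k], (shape[0] / grid, shape[1] / grid), order=3)
        field[k] -= field[k].mean()
    mag = np.hypot(field[0], field[1]).max()
    if mag > 0:
        field *= amplitude / mag
    return field


def _sample_warp(field: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear displacement lookup at (n, 2) points (y, x)."""
    coords = np.asarray(points, dtype=float).T  # (2, n)
    dy = ndimage.map_coordinates(field[0], coords, order=1, mode="nearest")
    dx = ndimage.map_coordinates(field[1], coords, order=1, mode="nearest")
    return np.stack([dy, dx], axis=1)


def _blob_params(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    sigma_range: tuple[float, float] = (1.6, 2.8),
    amp_range: tuple[float, float] = (120.0, 255.0),
    min_separation: float = 0.0,
):
    if min_separation > 0:  # rejection-sample separated centers (particle suspensions)
        placed: list[np.ndarray] = []
        attempts = 0
        while len(placed) < n and attempts < 200 * n:
            cand = np.array(
                [rng.uniform(margin, shape[0] - margin), rng.uniform(margin, shape[1] - margin)]
            )
            if all(np.linalg.norm(cand - p) >= min_separation for p in placed):
                placed.append(cand)
            attempts += 1
        if len(placed) < n:
            raise ValueError("could not place separated blobs; lower n or min_separation")
        centers = np.stack(placed)
    else:
        centers = np.stack(
            [
                rng.uniform(margin, shape[0] - margin, n),
                rng.uniform(margin, shape[1] - margin, n),
            ],
            axis=1,
        )
    base = rng.uniform(*sigma_range, n)
    aniso = rng.uniform(0.8, 1.25, n)
    sigmas = np.stack([base * aniso, base / aniso], axis=1)
    amps = rng.uniform(*amp_range, n)
    angles = rng.uniform(0, np.pi, n)
    return centers, sigmas, amps, angles


# ---------------------------------------------------------------------------
# generators


def gen_expansion_pair(
    n_objects: int = 60,
    scale: float = 4.0,
    rotation: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    warp_amplitude: float = 0.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    pre_shape: tuple[int, int] = (192, 192),
    n_planes: int = 12,
    pixel_size_xy: float = 0.1,
    min_separation: float = 0.0,
) -> tuple[np.ndarray, ImageStack, ExpansionPairTruth]:
    """Simulate a pre-expansion image and its post-expansion z-stack.

    The post image is the similarity transform (uniform ``scale``, ``rotation``
    about the frame centre, extra ``translation``) of the pre scene, plus an
    optional smooth non-rigid warp of max magnitude ``warp_amplitude`` px,
    rendered into a small z-stack whose middle planes carry the signal.
    ``keypoint_truth`` lists exact blob-centre correspondences.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not 1.0 <= scale <= 12.0:
        raise ValueError("scale outside the supported [1, 12] expansion range")
    if warp_amplitude < 0:
        raise ValueError("warp_amplitude must be >= 0")
    rng = np.random.default_rng(seed)

    margin = 12.0
    centers, sigmas, amps, angles = _blob_params(
        rng, n_objects, pre_shape, margin, min_separation=min_separation
    )
    pre = render_blobs(pre_shape, centers, sigmas, amps, angles)

    post_shape = (int(round(scale * pre_shape[0])), int(round(scale * pre_shape[1])))
    c_pre = (np.array(pre_shape, dtype=float) - 1) / 2
    c_post = (np.array(post_shape, dtype=float) - 1) / 2
    rot = SimilarityTransform(scale=scale, rotation=rotation, translation=(0.0, 0.0))
    t = c_post - rot.apply(c_pre[None])[0] + np.asarray(translation, dtype=float)
    transform = SimilarityTransform(scale=scale, rotation=rotation, translation=tuple(t))

    warp = smooth_warp_field(post_shape, warp_amplitude, rng)
    post_centers_rigid = transform.apply(centers)
    warp_disp = _sample_warp(warp, post_centers_rigid)
    post_centers = post_centers_rigid + warp_disp

    # signal concentrated in the middle planes with a smooth focus profile
    z_lo, z_hi = n_planes // 3, n_planes - n_planes // 3
    zc = (z_lo + z_hi - 1) / 2
    z_sigma = max((z_hi - z_lo) / 2.5, 0.8)
    plane_weights = np.exp(-0.5 * ((np.arange(n_planes) - zc) / z_sigma) ** 2)
    plane_weights /= plane_weights.max()  # best-focus plane carries the scene at unit gain

    post_plane = render_blobs(
        post_shape, post_centers, sigmas * scale, amps, angles + rotation
    )
    stack = np.zeros((1, n_planes) + post_shape, dtype=float)
    for z in range(n_planes):
        stack[0, z] = post_plane * plane_weights[z]
    if noise_sd > 0:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
        stack += rng.normal(0.0, noise_sd, stack.shape)
        stack = np.clip(stack, 0, None)

    post = ImageStack(
        data=stack,
        pixel_size_xy=pixel_size_xy,
        pixel_size_z=pixel_size_xy * 3,
        channel_names=["blobs"],
    )
    truth = ExpansionPairTruth(
        transform=transform,
        warp_amplitude=warp_amplitude,
        keypoint_truth=[(centers[i].copy(), post_centers[i].copy()) for i in range(n_objects)],
        content_z_window=(z_lo, z_hi),
        warp_displacements=warp_disp,
        warp_field=warp,
    )
    return pre, post, truth


def gen_round_series(
    n_rounds: int = 3,
    alpha_per_round: tuple[float, ...] = (0.4, 0.4),
    offsets: np.ndarray | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    n_blobs: int = 80,
):
    """Simulate cumulative-staining rounds obeying Image_i = R_i + a_i*Image_{i-1}.

    Each round's true signal ``R_i`` is an independent random blob field; the
    observed round accumulates a carry-over fraction ``alpha`` of the previous
    *observed* round (the recursion the unmixer inverts), then receives a rigid
    offset and noise. A nuclear reference channel shared by all rounds is
    included, as in multi-round imaging registered on a DAPI channel.

    Returns ``(rounds, truth)``: a list of 2-channel ImageStacks (channel 0
    ``DAPI``, channel 1 ``marker``) and a :class:`RoundSeriesTruth`.
    """
    if n_rounds < 2:
        raise ValueError("need at least 2 rounds")
    alpha = np.asarray(alpha_per_round, dtype=float)
    if alpha.shape != (n_rounds - 1,):
        raise ValueError("alpha_per_round must have length n_rounds - 1")
    if np.any(alpha < 0):
        raise ValueError("carry-over coefficients must be >= 0")
    if offsets is None:
        offsets = np.zeros((n_rounds, 2))
    offsets = np.asarray(offsets, dtype=float)
    rng = np.random.default_rng(seed)

    nuc = render_blobs(shape, *_blob_params(rng, max(6, n_blobs // 4), shape, 20.0, (6.0, 12.0)))
    true_fields = [
        render_blobs(shape, *_blob_params(rng, n_blobs, shape, 8.0)) for _ in range(n_rounds)
    ]

    rounds: list[ImageStack] = []
    truths: list[ImageStack] = []
    accumulated = None
    for i in range(n_rounds):
        accumulated = true_fields[i] if i == 0 else true_fields[i] + alpha[i - 1] * accumulated
        obs = np.stack([nuc, accumulated])
        if np.any(offsets[i]):
            obs = np.stack([ndimage.shift(ch, offsets[i], order=1, mode="constant") for ch in obs])
        if noise_sd > 0:
            obs = np.clip(obs + rng.normal(0.0, noise_sd, obs.shape), 0, None)
        rounds.append(ImageStack(obs, channel_names=["DAPI", "marker"]))
        truths.append(ImageStack(np.stack([nuc, true_fields[i]]), channel_names=["DAPI", "marker"]))
    truth = RoundSeriesTruth(alpha_per_round=alpha, true_images=truths, registration_offsets=offsets)
    return rounds, truth


def _nearest_voxels(shape, center, n, tie_break):
    """Flat indices of the n voxels nearest ``center`` (ties broken stably)."""
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center)).ravel()
    d2 = d2 + tie_break  # tiny jitter: deterministic, breaks lattice ties
    return np.argsort(d2, kind="stable")


def gen_label_volumes(
    shape: tuple[int, int, int] = (32, 64, 64),
    volumes: tuple[int, int] = (1000, 500),
    overlap_fraction: float = 0.5,
    seed: int = 0,
    centers: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Two compact binary volumes with an exactly controlled intersection.

    The intersection contains ``round(overlap_fraction * min(volumes))``
    voxels. Mask A is the ``vol_a`` voxels nearest a centre point; mask B takes
    its required overlap from the A voxels nearest a second centre and the rest
    from the nearest non-A voxels, yielding blob-like shapes with exact counts.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    vol_a, vol_b = (int(v) for v in volumes)
    n_total = int(np.prod(shape))
    overlap = int(round(overlap_fraction * min(vol_a, vol_b)))
    if vol_a + vol_b - overlap > n_total or min(vol_a, vol_b) <= 0:
        raise ValueError("requested volumes do not fit in the given shape")
    rng = np.random.default_rng(seed)
    if centers is None:
        c = (np.array(shape, dtype=float) - 1) / 2
        r_a = (3 * vol_a / (4 * np.pi)) ** (1 / 3)
        c_a = c - np.array([0.0, 0.0, r_a / 2])
        c_b = c + np.array([0.0, 0.0, r_a / 2])
    else:
        c_a, c_b = (np.asarray(x, dtype=float) for x in centers)

    jitter = rng.uniform(0, 1e-6, n_total)
    order_a = _nearest_voxels(shape, c_a, vol_a, jitter)
    mask_a = np.zeros(n_total, dtype=bool)
    mask_a[order_a[:vol_a]] = True

    order_b = _nearest_voxels(shape, c_b, vol_b, jitter)
    in_a = mask_a[order_b]
    idx_shared = order_b[in_a][:overlap]
    idx_outside = order_b[~in_a][: vol_b - overlap]
    if len(idx_shared) < overlap or len(idx_outside) < vol_b - overlap:
        raise ValueError("infeasible geometry for the requested overlap")
    mask_b = np.zeros(n_total, dtype=bool)
    mask_b[idx_shared] = True
    mask_b[idx_outside] = True

    mask_a = mask_a.reshape(shape)
    mask_b = mask_b.reshape(shape)
    truth = ColocTruth(overlap_voxels=int((mask_a & mask_b).sum()), vol_a=vol_a, vol_b=vol_b)
    return mask_a, mask_b, truth


def gen_blinking_movie(
    truth: EmitterTruth,
    n_frames: int = 100,
    background: float = 2.0,
    seed: int = 0,
    shape: tuple[int, int] = (48, 48),
    poisson: bool = True,
    frame_interval: float = 0.1,
) -> tuple[Movie, np.ndarray]:
    """Movie of independently blinking emitters under a Gaussian PSF.

    Emitters follow a two-state Markov chain (on->off with ``p_off``, off->on
    with ``p_on``) started from its stationary distribution; each frame sums
    the PSFs of the emitters that are on, plus ``background``, then is
    Poisson-sampled when ``poisson`` is true. Mirrors the 50-100 frame-per-plane
    acquisitions used for fluctuation imaging. Also returns the (t, n) boolean
    on-state matrix.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    n = len(truth.positions)
    p_stat = truth.p_on / (truth.p_on + truth.p_off) if (truth.p_on + truth.p_off) > 0 else 1.0
    state = rng.random(n) < p_stat
    states = np.zeros((n_frames, n), dtype=bool)
    for t in range(n_frames):
        states[t] = state
        u = rng.random(n)
        state = np.where(state, u >= truth.p_off, u < truth.p_on)

    sig = truth.psf_sigma
    sigmas = np.full((n, 2), sig)
    frames = np.empty((n_frames,) + shape, dtype=float)
    # render each emitter once, scale by its state per frame
    unit_imgs = [
        render_blobs(shape, truth.positions[i : i + 1], sigmas[i : i + 1], np.array([1.0]))
        for i in range(n)
    ]
    unit = np.stack(unit_imgs)  # (n, H, W)
    for t in range(n_frames):
        frames[t] = background + truth.photon_rate * np.tensordot(
            states[t].astype(float), unit, axes=1
        )
    if poisson:
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    return Movie(frames=frames, frame_interval=frame_interval), states


def gen_multiplexed_experiment(
    shape: tuple[int, int, int] = (24, 96, 96),
    n_rounds: int = 3,
    n_channels: int = 4,
    alpha: np.ndarray | None = None,
    offsets: np.ndarray | None = None,
    overlap_plan: list[tuple[tuple[int, int], tuple[int, int], float]] | None = None,
    marker_volume: int = 900,
    amplitude: float = 200.0,
    noise_sd: float = 2.0,
    seed: int = 0,
):
    """Full multi-round multiplexed experiment with known colocalization truth.

    Channel 0 is the nuclear reference (identical true signal in every round);
    channels 1..C-1 carry one marker per round. Markers named in
    ``overlap_plan`` entries ``((round_i, ch_i), (round_j, ch_j), fraction)``
    share a sub-volume with a controlled voxel overlap; all other marker pairs
    are disjoint by construction. Observed rounds accumulate per-channel
    carry-over ``alpha[(c-1), (r-1)]``, are rigidly offset per round, and
    noised — the exact conditions the register -> unmix -> colocalize pipeline
    must invert.
    """
    n_markers_per_round = n_channels - 1
    n_markers = n_markers_per_round * n_rounds
    if alpha is None:
        alpha = np.tile(np.linspace(0.3, 0.6, n_rounds - 1), (n_markers_per_round, 1))
    alpha = np.asarray(alpha, dtype=float)
    if offsets is None:
        offsets = np.array([[0, 0]] + [[3 * r, -2 * r] for r in range(1, n_rounds)], dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if overlap_plan is None:
        overlap_plan = [((0, 1), (0, 2), 0.5), ((1, 1), (1, 2), 0.3), ((2, 2), (2, 3), 0.7)]
    rng = np.random.default_rng(seed)

    # assign each marker (or overlapping pair) its own sub-volume block
    paired = {}
    for (a, b, f) in overlap_plan:
        paired[a] = (b, f)
        paired[b] = None
    all_markers = [(r, c) for r in range(n_rounds) for c in range(1, n_channels)]
    groups: list[tuple] = []
    for m in all_markers:
        if m in paired and paired[m] is not None:
            groups.append((m, *paired[m]))
        elif m not in paired:
            groups.append((m,))
    n_blocks = len(groups)
    bx = int(np.ceil(np.sqrt(n_blocks)))
    by = int(np.ceil(n_blocks / bx))
    block_h, block_w = shape[1] // by, shape[2] // bx

    masks = {f"r{r}c{c}": np.zeros(shape, dtype=bool) for r, c in all_markers}
    for gi, grp in enumerate(groups):
        oy, ox = (gi // bx) * block_h, (gi % bx) * block_w
        block_shape = (shape[0], block_h, block_w)
        if len(grp) == 1:
            (r, c) = grp[0]
            sub, _, _ = gen_label_volumes(
                block_shape, (marker_volume, marker_volume), 1.0, seed=rng.integers(2**31)
            )
            masks[f"r{r}c{c}"][:, oy : oy + block_h, ox : ox + block_w] = sub
        else:
            (ra, ca), (rb, cb), f = grp
            sub_a, sub_b, _ = gen_label_volumes(
                block_shape, (marker_volume, marker_volume), f, seed=rng.integers(2**31)
            )
            masks[f"r{ra}c{ca}"][:, oy : oy + block_h, ox : ox + block_w] = sub_a
            masks[f"r{rb}c{cb}"][:, oy : oy + block_h, ox : ox + block_w] = sub_b

    names = [f"r{r}c{c}" for r, c in all_markers]
    coloc = np.zeros((n_markers, n_markers))
    for i, ni in enumerate(names):
        vi = masks[ni].sum()
        for j, nj in enumerate(names):
            ov = (masks[ni] & masks[nj]).sum()
            coloc[i, j] = 100.0 * ov / vi if vi else 0.0

    # nuclear reference: blobby nuclei rendered per plane
    nuc = np.zeros(shape, dtype=float)
    ncent, nsig, namp, nang = _blob_params(
        rng, 8, shape[1:], 15.0, sigma_range=(7.0, 11.0), amp_range=(150.0, 220.0)
    )
    base = render_blobs(shape[1:], ncent, nsig, namp, nang)
    zprof = np.exp(-0.5 * ((np.arange(shape[0]) - (shape[0] - 1) / 2) / (shape[0] / 3)) ** 2)
    for z in range(shape[0]):
        nuc[z] = base * zprof[z]

    def render(mask):
        return ndimage.gaussian_filter(mask.astype(float) * amplitude, sigma=0.5)

    true_signals = {}
    for r in range(n_rounds):
        for c in range(1, n_channels):
            true_signals[(r, c)] = render(masks[f"r{r}c{c}"])

    rounds: list[ImageStack] = []
    accumulated = {c: None for c in range(1, n_channels)}
    for r in range(n_rounds):
        chans = [nuc]
        for c in range(1, n_channels):
            if r == 0:
                accumulated[c] = true_signals[(r, c)]
            else:
                accumulated[c] = true_signals[(r, c)] + alpha[c - 1, r - 1] * accumulated[c]
            chans.append(accumulated[c])
        obs = np.stack(chans)
        if np.any(offsets[r]):
            shift = (0.0, 0.0, offsets[r][0], offsets[r][1])
            obs = ndimage.shift(obs, shift, order=1, mode="constant")
        if noise_sd > 0:
            obs = np.clip(obs + rng.normal(0.0, noise_sd, obs.shape), 0, None)
        ch_names = ["DAPI"] + [f"marker{c}" for c in range(1, n_channels)]
        rounds.append(ImageStack(obs, channel_names=ch_names))

    truth = MultiplexTruth(
        marker_names=names,
        marker_masks=masks,
        alpha=alpha,
        offsets=offsets,
        coloc_matrix=coloc,
    )
    return rounds, truth
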