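# Methods

This note documents the models, estimators, numerical choices and known
limitations of the exmquant pipeline, and what its synthetic benchmarks do and
do not demonstrate about real microscope data.

## Conventions

Arrays are indexed `(channel, z, y, x)`; coordinates are `(y, x)`, 0-based,
pixel centres at integers; z-windows are half-open `[start, stop)`. Physical
pixel sizes are micrometres per pixel. Intensities are floats in memory with
the on-disk dtype recorded for write-back. Missing pixel-size metadata
defaults to 1.0 µm with a logged warning rather than failing or staying
silent.

## Distortion and expansion quantification

**Model.** An ideal expansion is a similarity transform: uniform scale *s*,
rotation, translation. Everything the best similarity fit cannot explain is
distortion. The 2D similarity is handled as complex multiplication
z → a·z + t (a = s·e^{iθ}), whose least-squares solution is the closed form
a = cov(z, w)/var(z) — the complex-regression form of the Procrustes problem.

**Pairing and consensus.** Pre/post pairs are matched with SIFT
(scikit-image) and a 0.8 ratio test with cross-checking. RANSAC uses 2-point
minimal samples (two points determine a similarity), a 3 px default inlier
tolerance in the post frame, up to 2000 iterations, and a recorded seed;
the winner is refit by least squares with one inlier re-selection pass. An
inlier fraction below 25% flags the result low-confidence; there is no
interactive alignment fallback — the error instructs supplying a transform.
Since the pre-expansion plane corresponds to an unknown span of post-expansion
planes, `find_best_z_projection` scans all contiguous z-windows with lengths
5–30 (maximum-intensity projection) and keeps the window with the most
similarity inliers.

**Subpixel refinement.** Keypoint detectors localise to roughly half a pixel,
which puts a ~0.3% floor under percent-distortion estimates. After the
similarity fit, the post image is resampled into the pre frame and each inlier
anchor is re-localised by phase correlation of 25×25 px patches at 1/20 px
resolution; the transform is then refit on the refined points. This lowers
the identity-pair noise floor to ≲0.1% and makes the recovered percent
distortion track the warp-derived truth within a few percent.

**RMS curve and the distortion scalar.** Up to 1e5 random anchor pairs are
sampled (seeded; all pairs when fewer); the measurement error of a pair is the
norm of the difference of its residual vectors, the measurement length is the
pre-frame anchor distance, bins are 1 µm wide. With several fields of view the
per-FOV curves are averaged per bin and the SEM is taken across FOVs (the
pooled-pair alternative weights FOVs by keypoint count; averaging FOV curves
was chosen so each replicate contributes equally, and the per-FOV curves
remain available). "Percent distortion" is not a standard scalar; here it is
rms(L)/L at the largest bin with ≥50 sampled pairs, recorded as such in
outputs.

**Expansion factors.** Four estimators: (i) keypoint — transform scale times
the post/pre pixel-size ratio; (ii) particle area — Otsu threshold (or a
supplied one) per image, connected-component areas with a 5 px minimum and a
relative gate at 10% of the median area (noise satellites split off particle
rims are tiny next to real particles), factor = sqrt of the mean-area ratio in
physical units; (iii) ratio of mean paired lengths; (iv) gross tissue-size
ratio. Normalizing to biological scale divides pixel sizes by the factor and
stores it in metadata; intensities are untouched, and successive
normalizations compose multiplicatively.

## SOFI

Order 2, zero time lag only. Physical pixels carry the temporal variance
(auto-cumulant); virtual pixels between horizontal, vertical and diagonal
neighbours carry the zero-lag cross-cumulant of their flanking pixels
(diagonal virtual pixels average the two crossing diagonals), giving a
(2H−1)×(2W−1) grid. Values follow the absolute-value convention. No
distance-factor flattening is applied — the benchmark quantities (FWHM ratio,
quadratic intensity scaling, nulls) are invariant to it. A temporally constant
movie yields an all-zero image with a warning, not an error.

Drift is estimated on means of 5-frame blocks (single blinking frames share
too little content with the temporal mean for per-frame registration): one
sequential block-to-block pass handles large monotonic drifts, kept only if
it sharpens the temporal mean (true drift does, spurious alignments of
blinking content do not), then up to three refinement passes against the
re-sharpened mean, all by amplitude (non-whitened) phase correlation at 0.1 px
resolution, linearly interpolated to frames. An estimated drift span above 25%
of the frame is a registration failure. Intensity correction divides each
frame by its spatial mean and rescales to the global mean; frames already at
the global mean are left bit-exact. Borders invalidated by the maximum applied
shift are cropped.

Deconvolution is standard Richardson–Lucy (scikit-image backend) with a
normalized Gaussian PSF, 10 iterations by default; the PSF width is estimated
from the intensity-weighted second moment of the brightest spot when not
given. Spot widths throughout are moment-based Gaussian sigmas; FWHM ratios
equal sigma ratios for Gaussian spots.

## Multi-round registration and unmixing

Rounds are aligned on the nuclear reference channel (max projections):
either SIFT + scale-locked (rigid) RANSAC, or translation-only iterative
phase correlation (amplitude-normalized — phase whitening is unstable on
smooth nuclear images), with automatic fallback from the first to the second.
Diffeomorphic demons (SimpleITK) refines residual non-rigid disagreement; it
runs in iteration chunks so a mean-squared residual rising three evaluations
running stops early with a warning, and 3D volumes are registered
plane-by-plane by default (each z-plane is a quasi-independent optical
section; full-3D would triple memory for little gain at these section
spacings). The field convention is u with warped(x) = moving(x + u(x)), so
the reference-channel field applies unchanged to the other channels of the
round.

**Carry-over search.** The coefficient grid is 0 : 0.01 : 1.5 and the search
is exhaustive enumeration; ties resolve to the smallest α. MI uses a 64×64
joint histogram of min–max-normalized intensities, in nats. Three estimator
details matter and are defaults of `find_alpha_opt`:

1. the residual inside the MI argument is the raw subtraction
   Image_i − α·Image_{i−1}; clipping it to zero before scoring deletes the
   anti-correlated negative lobe that is the evidence of over-subtraction and
   makes the profile decrease monotonically past the true α on sparse images.
   Non-negativity is enforced on the *output* images only;
2. both images are smoothed with a σ = 1.5 px Gaussian first: per-voxel noise
   enters both MI arguments through the subtraction and otherwise attenuates
   the recovered α by a few hundredths (the errors-in-variables effect);
3. the joint histogram is built only from voxels carrying signal in either
   round (>10% of the image maximum, after subtracting the 1st-percentile
   background floor): the background voxel mass otherwise dominates the
   histogram and the quantisation of its bin assignment makes the MI profile
   jagged.

Under these defaults the recovered α is within 0.02 (usually 0.01) of truth
for α ∈ [0.1, 1.0] on 256² rounds at the generator's noise level. α is
searched per detection channel (channels are stained independently, so their
carry-over need not be equal); the reference channel is never unmixed.

## Colocalization

A voxel is foreground iff its value exceeds the local mean over a 31-voxel
cubic window scaled by (1 + (1 − sensitivity)) — sensitivity 0.5 by default,
per-channel override — **and** exceeds a global floor (Otsu by default, a
number per channel, or disabled). The floor exists because a purely relative
criterion marks large swaths of flat background as foreground (any noise voxel
above its local noise mean), which percolates into one giant 26-connected
component; it plays the role of the background subtraction that precedes
colocalization in practice. Components under 27 voxels (3³) are removed,
labels renumbered contiguously; an all-background channel is a valid empty
volume, zeroing its row and column with a flag.

The colocalization index is exact integer voxel arithmetic. Matrix entry
(i, j) is the percentage of channel i's particle volume overlapped by channel
j (row = reference channel, recorded in metadata; the matrix is generally
asymmetric and both directions are present as (i, j) and (j, i)). Group
analysis averages matrices across ROIs, takes delta = mean(group2) −
mean(group1), and tests each cell with a one-way ANOVA across ROIs — with two
groups this is the F-test with (1, n−2) degrees of freedom. No
multiple-testing correction by default (a Benjamini–Hochberg option exists).
Cells with zero variance across all ROIs get p = 1 and a degenerate flag.
Vacuole-level analysis is supported by running `coloc_index` on cropped
subvolumes; automated vacuole detection is out of scope.

## Synthetic data: what it emulates and what it does not

All generators are deterministic given a seed, and their truth records
suffice to score every downstream estimate without re-simulation.

- **Expansion pairs**: anisotropic Gaussian blobs (keypoint detectors need
  texture) in a 192² pre frame; the post stack renders the blobs at the
  transformed positions into scale×192 squared frames and 12 z-planes with a
  Gaussian focus profile (unit gain at best focus), Poisson + Gaussian noise
  (σ = 2 counts — cameras' noise statistics are not published for the class of
  experiment emulated, so a realistic read-noise figure was fixed once). The
  non-rigid warp is a 5×5 random displacement lattice upsampled with cubic
  splines, zero-mean, rescaled so its maximum magnitude equals the requested
  amplitude — distortion as one controllable scalar.
- **Particle suspensions** (for the area method): separated plateau-topped
  discs with sigmoid rims; the rim width scales with the expansion so the post
  image is self-similar to the pre image. Gaussian blobs are deliberately not
  used here: a Gaussian's thresholded area depends on the threshold, a
  plateau's does not.
- **Round series**: independent blob fields per round, accumulated with the
  recursive carry-over applied to the *observed* previous round, then rigidly
  offset and noised; a shared nuclear channel is included for registration.
- **Blinking movies**: two-state Markov emitters (off→on p_on, on→off p_off)
  started from the stationary distribution, Gaussian PSFs, optional Poisson
  sampling; 50–100 frames per plane is the emulated regime.
- **Label volumes**: mask A is the volA voxels nearest a centre; mask B takes
  exactly round(f·min(volA, volB)) voxels of A nearest a second centre plus
  the nearest outside voxels — blob-like shapes with exact voxel counts.
- **Multiplexed experiment**: 3 rounds × 4 channels (nuclear reference +
  3 markers/round) in a 24×96×96 volume; markers live in disjoint sub-blocks
  except planned pairs with controlled overlap; per-channel carry-over
  (0.3, 0.6), per-round integer offsets, σ = 2 noise.

Not emulated: realistic cell morphology, photobleaching and chemical
signal-stripping, spectral bleed-through between simultaneous channels, 3D
optical sectioning and depth-dependent aberrations, tiling/stitching
artefacts, or rotation between imaging rounds (stages reposition, they do not
rotate; the keypoint path would absorb small rotations if present). Passing
benchmarks therefore demonstrate the estimators' correctness and calibration
under controlled conditions, not robustness to every pathology of real data.

## Benchmark problem sizes

The reproduction script and the validation suite use: 256² rounds, 10 α values
× 5 seeds; expansion scales {2, 4, 6, 8} with 128² pre frames; 10 warp
fixtures at 3 px amplitude; 80-point RANSAC sets with 30% outliers; 300-frame
single-emitter movies; 100 random 16³ mask pairs; 64² demons fields at 3 px
warp; one full 9-marker multiplexed experiment. The warp-derived distortion
truth is evaluated at the same anchor points the pipeline selected, because
the smooth warp has few independent patches and different spatial samplings
of it measure genuinely different RMS values.

## Known limitations

- SIFT on very small (≲96²) or low-texture images finds few keypoints; the
  translation-only registration mode is the fallback.
- The α search assumes registered rounds; residual misalignment of ≳1 px
  biases α low (the subtraction can no longer cancel the carry-over).
- Percent distortion from a single field of view inherits the keypoint-set
  sampling variance of the warp; replicate FOVs are averaged in practice.
- Demons recovers displacement only where intensity gradients exist; endpoint
  errors are meaningful on signal-carrying pixels, and are evaluated there.
- The adaptive-threshold window must remain large relative to the objects;
  objects comparable to the window raise the local mean enough to eat their
  own interiors.
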