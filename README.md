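# exmquant

Quantitative image analysis for expansion microscopy (ExM) experiments, with a
focus on multiplexed imaging of microbial and infected-cell specimens. In ExM a
specimen is embedded in a swellable hydrogel and physically enlarged several
fold, so that conventional confocal optics resolve nanoscale structure. The
numbers that make such an experiment trustworthy — how isotropic the expansion
was, what the expansion factor is, how cleanly sequential staining rounds can
be separated, and which markers colocalize — all come from image analysis, and
this package implements that analysis as a tested library:

- **Distortion and expansion factor** (`exmquant.distortion`): pre- and
  post-expansion images are paired by SIFT keypoints filtered with RANSAC under
  a similarity model (rotation + translation + uniform scale *s* — the physical
  model of isotropic expansion). The residual vectors after the best similarity
  fit form the distortion field; differencing residuals of point pairs gives
  the RMS length-measurement error as a function of measurement length,
  rms(L) = sqrt(E[ ||v_i − v_j||² ]) over pairs at distance L. The linear
  expansion factor is estimated from the transform scale, from particle-area
  ratios (factor = sqrt(mean post area / mean pre area)), from paired length
  samples, or from gross tissue size.
- **SOFI** (`exmquant.sofi`): second-order cumulant super-resolution
  reconstruction of blinking-emitter movies, XC2(a) = ⟨δF_a(t)²⟩ with
  δF = F − ⟨F⟩_t, cross-cumulants ⟨δF_a δF_b⟩ on a 2× virtual grid, preceded by
  drift/intensity correction and followed by Richardson–Lucy deconvolution.
- **Registration** (`exmquant.registration`): keypoint similarity fitting,
  best-z-projection search for pre/post pairing, rigid multi-round alignment
  on a nuclear reference channel, and diffeomorphic-demons refinement whose
  displacement field transfers to the other channels of the same round.
- **Signal unmixing for cumulative staining** (`exmquant.flunmix`): when
  rounds are imaged without stripping the previous stain, the observed image
  accumulates Image_i = R_i + α·Image_{i−1}. The carry-over coefficient is
  found by enumerating candidates and minimizing the mutual information
  α_opt = argmin_α I(Image_{i−1}; Image_i − α·Image_{i−1}), and the true
  signal is R_i = clip(Image_i − α_opt·Image_{i−1}, 0).
- **3D colocalization** (`exmquant.colocalization`): adaptive local
  thresholding, 26-connected particle labeling with size filters, directional
  volume-overlap percentages (100·|A∩B|/|A|, generally asymmetric), C×C
  matrices per region of interest, group means, delta matrices and per-cell
  one-way ANOVA with 0.05/0.01/0.001 significance stars.
- **Synthetic data** (`exmquant.synthetic`): seeded generators with exact
  ground truth for every stage — expansion pairs with controlled non-rigid
  warp, particle suspensions, cumulative staining rounds, blinking-emitter
  movies, label volumes with exact voxel overlaps, and a full multi-round
  multiplexed experiment.

## Worked example

Recover a carry-over coefficient from two simulated staining rounds:

```python
from exmquant import synthetic as syn
from exmquant.flunmix import find_alpha_opt

rounds, truth = syn.gen_round_series(n_rounds=2, alpha_per_round=(0.4,), seed=1)
fit = find_alpha_opt(rounds[0].channel("marker")[0], rounds[1].channel("marker")[0])
print(truth.alpha_per_round[0], fit.alpha_opt)
```

prints

```
0.4 0.4
```

the true carry-over fraction and the coefficient recovered by MI enumeration
(grid step 0.01). The analysis drivers under `analysis/` run each stage as a
narrative script; for example `python analysis/02_distortion_expansion.py`
prints

```
 true_scale  keypoint_factor  particle_area_factor  n_inlier_matches  percent_distortion
        2.0           2.0025                1.9933                91              0.6201
        4.0           4.0079                3.9615                87              0.4680
        6.0           5.9956                5.9553                75              0.1901
        8.0           7.9874                7.9170                76              0.2098
```

— both expansion-factor estimators recover the simulated scale to well under
1% (keypoint) and ~1% (particle area), and the plateau percent distortion of
the injected 3 px warp stays below 1% of the measurement length, the regime a
well-behaved expansion protocol operates in. `analysis/05_colocalization.py`
runs the full register → unmix → colocalize pipeline on two simulated groups
and reproduces a planned 40-percentage-point drop in one marker pair's overlap
with p < 1e-11 in the delta-matrix ANOVA.

There is also a thin CLI (`exmquant io-info | simulate | sofi | register-pair |
distortion | flunmix | coloc`) over the same library calls.

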