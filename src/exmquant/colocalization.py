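"""3D volume-overlap colocalization: segmentation, indices, matrices, statistics.

Each channel of a registered multichannel volume is binarized by adaptive
local thresholding, labeled into particles under 26-connectivity (voxels
sharing a face, edge or corner are connected) and size-filtered. The
colocalization index of an ordered channel pair is the intersection volume as
a percentage of each channel's particle volume; assembling all ordered pairs
gives a generally asymmetric C x C matrix per region of interest (ROI).
Group-level analysis averages matrices across ROIs, forms the delta matrix
between two conditions, and scores each cell with a one-way ANOVA across ROIs
(two groups: equivalent to the F-test with 1 and n-2 degrees of freedom),
starred at p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_otsu

__all__ = [
    "LabelVolume",
    "ColocMatrix",
    "DeltaResult",
    "binarize_and_label",
    "coloc_index",
    "coloc_matrix",
    "delta_matrix_anova",
]

CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LabelVolume:
    """26-connected particle labels (0 = background), contiguous 1..n."""

    labels: np.ndarray
    n_particles: int
    particle_sizes: np.ndarray  # voxels per label, index k -> label k+1

    @property
    def foreground(self) -> np.ndarray:
        return self.labels > 0

    @property
    def total_volume(self) -> int:
        return int(self.particle_sizes.sum())


@dataclass
class ColocMatrix:
    """C x C volume-overlap percentages for one ROI.

    ``values[i, j]`` is the percentage of channel i's particle volume that is
    overlapped by channel j (row = reference channel); the convention is
    recorded here because the directional index is asymmetric.
    """

    values: np.ndarray
    channel_names: list[str]
    roi_id: str = ""
    empty_channels: list[str] = field(default_factory=list)


@dataclass
class DeltaResult:
    """Group comparison of colocalization matrices across ROIs."""

    mean_group1: np.ndarray
    mean_group2: np.ndarray
    delta: np.ndarray  # mean(group2) - mean(group1)
    p_values: np.ndarray
    stars: np.ndarray  # '', '*', '**', '***'
    channel_names: list[str]
    degenerate: np.ndarray | None = None  # cells where all ROI values coincide


def binarize_and_label(
    volume: np.ndarray,
    sensitivity: float = 0.5,
    window: int = 31,
    min_size: int = 27,
    global_floor: float | str | None = "otsu",
) -> LabelVolume:
    """Adaptive local thresholding + 26-connected labeling + size filter.

    A voxel is foreground iff its value exceeds the local mean over a cubic
    ``window`` scaled by ``1 + (1 - sensitivity)``: at sensitivity 1 any voxel
    above its local mean passes, lower sensitivity demands proportionally more
    contrast (the knob to adjust per channel signal-to-noise). A purely
    relative criterion marks large swaths of flat background noise as
    foreground (any voxel above its local noise mean), so an additional global
    intensity floor is applied — Otsu's threshold by default, a number to fix
    it per channel, ``None`` to disable (it then behaves like raw adaptive
    thresholding on background-subtracted data). Components smaller than
    ``min_size`` voxels are removed and labels renumbered contiguously. An
    all-background result is a valid empty LabelVolume.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must lie in [0, 1]")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    local_mean = ndimage.uniform_filter(vol, size=window, mode="reflect")
    fg = vol > local_mean * (1.0 + (1.0 - sensitivity))
    if global_floor is not None:
        floor = threshold_otsu(vol) if global_floor == "otsu" else float(global_floor)
        fg &= vol > floor
    labels, n = ndimage.label(fg, structure=CONNECTIVITY_26)
    if n == 0:
        return LabelVolume(labels=labels, n_particles=0, particle_sizes=np.zeros(0, int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.where(sizes >= min_size)[0] + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]
    return LabelVolume(
        labels=labels,
        n_particles=len(keep),
        particle_sizes=sizes[keep - 1].astype(int),
    )


def coloc_index(a: LabelVolume, b: LabelVolume) -> tuple[float, float]:
    """Directional volume-overlap percentages of two particle volumes.

    With O the voxel count of the two foregrounds' intersection, returns
    ``(100*O/|A|, 100*O/|B|)``; an empty channel contributes 0. Exact integer
    voxel arithmetic.
    """
    if a.labels.shape != b.labels.shape:
        raise ValueError("label volumes must share a shape")
    fa, fb = a.foreground, b.foreground
    na, nb = int(fa.sum()), int(fb.sum())
    overlap = int((fa & fb).sum())
    pct_in_a = 100.0 * overlap / na if na else 0.0
    pct_in_b = 100.0 * overlap / nb if nb else 0.0
    return pct_in_a, pct_in_b


def coloc_matrix(
    stack,
    per_channel_params: dict[str, dict] | None = None,
    roi_id: str = "",
    channels: list[str] | None = None,
) -> ColocMatrix:
    """C x C colocalization matrix over the channels of an ImageStack.

    Each channel is segmented with its own parameters (``sensitivity``,
    ``window``, ``min_size``); entry (i, j) is the percentage of channel i's
    volume overlapped by channel j. The diagonal of a non-empty channel is
    100 by construction; empty channels zero their row and column and are
    flagged.
    """
    names = channels if channels is not None else list(stack.channel_names)
    if len(names) < 2:
        raise ValueError("need at least 2 channels")
    params = per_channel_params or {}
    labeled = {}
    for name in names:
        labeled[name] = binarize_and_label(np.asarray(stack.channel(name)), **params.get(name, {}))
    c = len(names)
    values = np.zeros((c, c))
    empty = [n for n in names if labeled[n].n_particles == 0]
    for i, ni in enumerate(names):
        for j, nj in enumerate(names):
            if j < i:
                continue
            pct_i, pct_j = coloc_index(labeled[ni], labeled[nj])
            values[i, j] = pct_i
            values[j, i] = pct_j
    return ColocMatrix(values=values, channel_names=names, roi_id=roi_id, empty_channels=empty)


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def delta_matrix_anova(
    group1: list[ColocMatrix],
    group2: list[ColocMatrix],
    bh_correct: bool = False,
) -> DeltaResult:
    """Per-cell group means, delta matrix, and one-way ANOVA significance.

    Each ROI contributes one matrix per group; per matrix cell the ROI-level
    values of the two groups enter a one-way ANOVA (two groups, so the F-test
    with 1 and n-2 df). Cells whose values coincide exactly across all ROIs
    have no variance to test: p = 1, flagged degenerate. Stars follow
    0.05/0.01/0.001. ``bh_correct`` optionally applies Benjamini-Hochberg
    across the off-diagonal cells (off by default).
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("need at least 2 ROIs per group")
    names = group1[0].channel_names
    for m in group1 + group2:
        if m.channel_names != names:
            raise ValueError("all matrices must share channel names")
    g1 = np.stack([m.values for m in group1])  # (n1, C, C)
    g2 = np.stack([m.values for m in group2])
    mean1, mean2 = g1.mean(axis=0), g2.mean(axis=0)
    delta = mean2 - mean1
    c = len(names)
    p = np.ones((c, c))
    degen = np.zeros((c, c), dtype=bool)
    for i in range(c):
        for j in range(c):
            x, y = g1[:, i, j], g2[:, i, j]
            if np.ptp(np.concatenate([x, y])) == 0:
                degen[i, j] = True
                continue
            p[i, j] = stats.f_oneway(x, y).pvalue
    if bh_correct:
        off = ~np.eye(c, dtype=bool)
        from statsmodels.stats.multitest import multipletests

        p_off = p[off]
        p[off] = multipletests(p_off, method="fdr_bh")[1]
    stars = np.full((c, c), "", dtype=object)
    for thresh, mark in _STAR_LEVELS:
        stars[(p < thresh) & (stars == "")] = mark
    stars[degen] = ""
    return DeltaResult(
        mean_group1=mean1,
        mean_group2=mean2,
        delta=delta,
        p_values=p,
        stars=stars,
        channel_names=names,
        degenerate=degen,
    )
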