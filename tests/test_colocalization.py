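import numpy as np
import pytest
from scipy import stats

from exmquant import synthetic as syn
from exmquant.colocalization import (
    ColocMatrix,
    LabelVolume,
    binarize_and_label,
    coloc_index,
    coloc_matrix,
    delta_matrix_anova,
)
from exmquant.image_io import ImageStack


def label_volume_from_mask(mask):
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return LabelVolume(labels=labels, n_particles=n, particle_sizes=sizes.astype(int))


def flood_fill_label(mask):
    """Independent 26-connectivity labeling by explicit BFS flood fill."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not labels[nz, ny, nx]
                ):
                    labels[nz, ny, nx] = current
                    stack.append((nz, ny, nx))
    return labels, current


class TestBinarizeAndLabel:
    def test_bright_cube_is_one_particle_of_exact_size(self):
        vol = np.zeros((16, 16, 16))
        vol[6:10, 6:10, 6:10] = 100.0
        lv = binarize_and_label(vol, window=9, min_size=27)
        assert lv.n_particles == 1
        assert lv.particle_sizes.tolist() == [64]

    def test_corner_touching_cubes_connect_under_26_connectivity(self):
        vol = np.zeros((16, 16, 16))
        vol[4:7, 4:7, 4:7] = 100.0
        vol[7:10, 7:10, 7:10] = 100.0  # shares only the corner voxel adjacency
        lv = binarize_and_label(vol, window=9, min_size=27)
        assert lv.n_particles == 1

    def test_min_size_filter_boundary(self):
        vol = np.zeros((16, 16, 16))
        vol[2:4, 2:4, 2:4] = 100.0  # 8-voxel speck
        vol[8:11, 8:11, 8:11] = 100.0  # 27-voxel cube
        lv = binarize_and_label(vol, window=9, min_size=27)
        assert lv.n_particles == 1
        assert lv.particle_sizes.tolist() == [27]

    def test_empty_volume_is_valid_and_empty(self):
        lv = binarize_and_label(np.zeros((8, 8, 8)), window=5)
        assert lv.n_particles == 0
        assert lv.total_volume == 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="window"):
            binarize_and_label(np.zeros((8, 8, 8)), window=4)
        with pytest.raises(ValueError, match="sensitivity"):
            binarize_and_label(np.zeros((8, 8, 8)), sensitivity=1.5)

    def test_labeling_agrees_with_flood_fill_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = rng.random((16, 16, 16)) < 0.08
            vol = mask * 100.0
            lv = binarize_and_label(vol, window=9, min_size=1, global_floor=50.0)
            _, n_oracle = flood_fill_label(mask)
            assert lv.n_particles == n_oracle
            assert np.array_equal(lv.foreground, mask)


class TestColocIndex:
    def test_constructed_overlap_returns_exact_percentages(self):
        a, b, _ = syn.gen_label_volumes((32, 64, 64), (1000, 500), 0.5, seed=0)
        pct = coloc_index(label_volume_from_mask(a), label_volume_from_mask(b))
        assert pct == (25.0, 50.0)

    def test_identical_and_disjoint_masks(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        lv = label_volume_from_mask(mask)
        assert coloc_index(lv, lv) == (100.0, 100.0)
        other = np.zeros_like(mask)
        other[6:8, 6:8, 6:8] = True
        assert coloc_index(lv, label_volume_from_mask(other)) == (0.0, 0.0)

    def test_matches_brute_force_voxel_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            a = rng.random((16, 16, 16)) < 0.2
            b = rng.random((16, 16, 16)) < 0.2
            pa, pb = coloc_index(label_volume_from_mask(a), label_volume_from_mask(b))
            overlap = sum(
                1
                for z in range(16)
                for y in range(16)
                for x in range(16)
                if a[z, y, x] and b[z, y, x]
            )
            assert pa == 100.0 * overlap / a.sum()
            assert pb == 100.0 * overlap / b.sum()

    def test_empty_channel_contributes_zero(self):
        empty = label_volume_from_mask(np.zeros((4, 4, 4), bool))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        assert coloc_index(empty, label_volume_from_mask(mask)) == (0.0, 0.0)

    def test_shape_mismatch_rejected(self):
        a = label_volume_from_mask(np.zeros((4, 4, 4), bool))
        b = label_volume_from_mask(np.zeros((5, 4, 4), bool))
        with pytest.raises(ValueError):
            coloc_index(a, b)


class TestColocMatrix:
    def make_stack(self, masks, names):
        data = np.stack([m * 100.0 for m in masks])
        return ImageStack(data, channel_names=names)

    def test_identical_channels_are_fully_colocalized(self):
        mask = np.zeros((12, 24, 24))
        mask[4:8, 8:16, 8:16] = 1.0
        stack = self.make_stack([mask] * 3, ["a", "b", "c"])
        mat = coloc_matrix(stack, {n: {"window": 9} for n in "abc"})
        assert np.allclose(mat.values, 100.0)

    def test_matrix_matches_generator_truth(self):
        a, b, truth = syn.gen_label_volumes((16, 32, 32), (600, 400), 0.5, seed=2)
        stack = self.make_stack([a.astype(float), b.astype(float)], ["a", "b"])
        # window must stay large next to the object so the local mean reflects
        # background, not the object interior
        mat = coloc_matrix(stack, {n: {"window": 15} for n in "ab"})
        assert mat.values[0, 1] == pytest.approx(100 * truth.fraction_in_a, abs=0.5)
        assert mat.values[1, 0] == pytest.approx(100 * truth.fraction_in_b, abs=0.5)

    def test_channel_permutation_permutes_matrix(self):
        rng = np.random.default_rng(3)
        masks = [rng.random((8, 16, 16)) < 0.2 for _ in range(3)]
        stack = self.make_stack([m.astype(float) for m in masks], ["a", "b", "c"])
        params = {n: {"window": 9, "min_size": 1} for n in "abc"}
        m1 = coloc_matrix(stack, params)
        perm = [2, 0, 1]
        stack_p = self.make_stack([masks[i].astype(float) for i in perm], ["c", "a", "b"])
        m2 = coloc_matrix(stack_p, params)
        p = np.zeros((3, 3))
        for new_i, old_i in enumerate(perm):
            p[new_i, old_i] = 1
        assert np.allclose(m2.values, p @ m1.values @ p.T)

    def test_ten_channel_panel_yields_ten_by_ten(self):
        rng = np.random.default_rng(4)
        masks = [rng.random((6, 16, 16)) < 0.15 for _ in range(10)]
        stack = self.make_stack([m.astype(float) for m in masks], [f"ch{i}" for i in range(10)])
        mat = coloc_matrix(stack, {f"ch{i}": {"window": 9, "min_size": 1} for i in range(10)})
        assert mat.values.shape == (10, 10)
        assert np.allclose(np.diag(mat.values), 100.0)

    def test_empty_channel_flagged(self):
        mask = np.zeros((8, 16, 16))
        mask[2:5, 4:10, 4:10] = 1.0
        stack = self.make_stack([mask, np.zeros_like(mask)], ["full", "empty"])
        mat = coloc_matrix(stack, {n: {"window": 9} for n in ("full", "empty")})
        assert "empty" in mat.empty_channels
        assert np.all(mat.values[1] == 0) and np.all(mat.values[:, 1] == 0)


class TestDeltaMatrixAnova:
    def roi_matrices(self, means, sd, n, seed, names=("a", "b")):
        rng = np.random.default_rng(seed)
        out = []
        for k in range(n):
            vals = np.clip(rng.normal(means, sd), 0, 100)
            np.fill_diagonal(vals, 100.0)
            out.append(ColocMatrix(values=vals, channel_names=list(names), roi_id=str(k)))
        return out

    def test_identical_groups_have_zero_delta_and_no_stars(self):
        g = self.roi_matrices(np.array([[100.0, 40.0], [30.0, 100.0]]), 5.0, 4, seed=0)
        res = delta_matrix_anova(g, g)
        assert np.allclose(res.delta, 0)
        assert (res.stars == "").all()

    def test_large_shift_detected_with_high_significance(self):
        base = np.array([[100.0, 40.0], [30.0, 100.0]])
        g1 = self.roi_matrices(base, 5.0, 10, seed=1)
        g2 = self.roi_matrices(base + 30 * (1 - np.eye(2)), 5.0, 10, seed=2)
        res = delta_matrix_anova(g1, g2)
        assert res.delta[0, 1] == pytest.approx(30.0, abs=8.0)
        assert res.stars[0, 1] == "***"

    def test_pvalues_match_closed_form_f_distribution(self):
        g1 = self.roi_matrices(np.array([[100.0, 35.0], [20.0, 100.0]]), 6.0, 5, seed=3)
        g2 = self.roi_matrices(np.array([[100.0, 55.0], [25.0, 100.0]]), 6.0, 7, seed=4)
        res = delta_matrix_anova(g1, g2)
        x = np.array([m.values[0, 1] for m in g1])
        y = np.array([m.values[0, 1] for m in g2])
        # hand-computed one-way ANOVA F statistic for two groups
        grand = np.concatenate([x, y]).mean()
        ss_between = len(x) * (x.mean() - grand) ** 2 + len(y) * (y.mean() - grand) ** 2
        ss_within = ((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()
        df1, df2 = 1, len(x) + len(y) - 2
        f_stat = (ss_between / df1) / (ss_within / df2)
        p_oracle = stats.f.sf(f_stat, df1, df2)
        assert res.p_values[0, 1] == pytest.approx(p_oracle, abs=1e-10)

    def test_study_sized_groups_run(self):
        g1 = self.roi_matrices(np.array([[100.0, 50.0], [45.0, 100.0]]), 4.0, 3, seed=5)
        g2 = self.roi_matrices(np.array([[100.0, 20.0], [15.0, 100.0]]), 4.0, 3, seed=6)
        res = delta_matrix_anova(g1, g2)
        assert res.p_values.shape == (2, 2)

    def test_degenerate_cells_flagged_with_p_one(self):
        g1 = self.roi_matrices(np.array([[100.0, 40.0], [30.0, 100.0]]), 0.0, 3, seed=7)
        res = delta_matrix_anova(g1, g1)
        assert res.degenerate.all()
        assert np.all(res.p_values == 1.0)

    def test_too_few_rois_rejected(self):
        g = self.roi_matrices(np.array([[100.0, 40.0], [30.0, 100.0]]), 5.0, 1, seed=8)
        with pytest.raises(ValueError):
            delta_matrix_anova(g, g)
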