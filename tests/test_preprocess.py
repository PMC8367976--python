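"""Smoothing, Otsu segmentation, inertia alignment, regions and VOI grids."""

import numpy as np
import pytest
from scipy import ndimage

from enthemorph.preprocess import (
    RegionSpec,
    align_principal_axes,
    binarize,
    define_tuberosity,
    gaussian_smooth,
    marching_voi_grid,
    otsu_threshold,
    voi_span_mm,
)
from enthemorph.volume import BinaryVolume, VoxelVolume


class TestGaussianSmooth:
    def test_constant_volume_unchanged(self):
        v = VoxelVolume(np.full((20, 20, 20), 7.0), 1.0)
        out = gaussian_smooth(v)
        assert np.allclose(out.grid, 7.0)

    def test_impulse_response_symmetric_and_sum_preserving(self):
        g = np.zeros((21, 21, 21))
        g[10, 10, 10] = 1.0
        out = gaussian_smooth(VoxelVolume(g, 1.0)).grid
        assert out.sum() == pytest.approx(1.0, rel=1e-9)
        assert np.allclose(out, out[::-1, :, :])
        assert np.allclose(out, np.transpose(out, (1, 0, 2)))

    def test_noise_variance_strictly_decreases(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            g = rng.normal(size=(30, 30, 30))
            out = gaussian_smooth(VoxelVolume(g, 1.0)).grid
            assert out.std() < g.std()


class TestOtsu:
    def test_two_valued_volume_separates_exactly(self):
        rng = np.random.default_rng(0)
        g = np.where(rng.uniform(size=(20, 20, 20)) < 0.4, 10.0, 200.0)
        thr = otsu_threshold(VoxelVolume(g, 1.0))
        assert 10.0 <= thr < 200.0
        seg = binarize(VoxelVolume(g, 1.0), thr)
        assert np.array_equal(seg.grid, g == 200.0)

    def test_matches_exhaustive_search_on_bimodal_histograms(self):
        """Otsu equals brute-force maximization of between-class variance."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            g = np.concatenate(
                [rng.normal(60, 12, 4000), rng.normal(180, 18, 6000)]
            ).clip(0, 255).round()
            thr = otsu_threshold(VoxelVolume(g.reshape(10, 10, 100), 1.0), nbins=256)
            # brute force over all candidate levels
            best, best_var = None, -1.0
            for t in np.unique(g)[:-1]:
                w0 = (g <= t).mean()
                w1 = 1 - w0
                if w0 == 0 or w1 == 0:
                    continue
                var = w0 * w1 * (g[g <= t].mean() - g[g > t].mean()) ** 2
                if var > best_var:
                    best_var, best = var, t
            # the returned threshold must classify identically to the oracle's
            assert np.array_equal(g > thr, g > best)

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(VoxelVolume(np.full((5, 5, 5), 3.0), 1.0))


class TestAlignment:
    @staticmethod
    def _box(shape=(100, 100, 60), ext=(40, 20, 12)):
        g = np.zeros(shape, bool)
        c = [s // 2 for s in shape]
        g[c[0] - ext[0] // 2 : c[0] + ext[0] // 2,
          c[1] - ext[1] // 2 : c[1] + ext[1] // 2,
          c[2] - ext[2] // 2 : c[2] + ext[2] // 2] = True
        return g

    def test_axis_aligned_box_keeps_identity_up_to_permutation(self):
        b = BinaryVolume(self._box(), 1.0)
        aligned, frame = align_principal_axes(b)
        assert np.allclose(np.abs(frame.rotation), np.eye(3), atol=1e-6)

    def test_rotated_box_recovered_within_one_degree(self):
        g = self._box()
        rot = ndimage.rotate(g.astype(np.uint8), 30, axes=(0, 1), order=0,
                             reshape=False).astype(bool)
        aligned, frame = align_principal_axes(BinaryVolume(rot, 1.0))
        # long axis back on x: extents match the constructed box
        coords = np.argwhere(aligned.grid)
        ext = coords.max(axis=0) - coords.min(axis=0)
        assert abs(ext[0] - 40) <= 2 and ext[0] > ext[1] > ext[2]
        # recovered rotation magnitude equals the constructed 30° within 1°
        ang = np.degrees(np.arccos(np.clip((np.trace(frame.rotation) - 1) / 2, -1, 1)))
        assert ang == pytest.approx(30.0, abs=1.0)

    def test_realignment_is_idempotent(self):
        g = self._box()
        rot = ndimage.rotate(g.astype(np.uint8), 25, axes=(0, 1), order=0,
                             reshape=False).astype(bool)
        aligned, _ = align_principal_axes(BinaryVolume(rot, 1.0))
        _, frame2 = align_principal_axes(aligned)
        ang = np.degrees(np.arccos(np.clip((np.trace(frame2.rotation) - 1) / 2, -1, 1)))
        assert ang < 0.5

    def test_aligned_inertia_tensor_nearly_diagonal(self):
        g = self._box()
        rot = ndimage.rotate(g.astype(np.uint8), 40, axes=(0, 1), order=0,
                             reshape=False).astype(bool)
        aligned, _ = align_principal_axes(BinaryVolume(rot, 1.0))
        coords = np.argwhere(aligned.grid).astype(float)
        c = coords - coords.mean(axis=0)
        cov = c.T @ c / len(c)
        off = np.abs(cov - np.diag(np.diag(cov))).max()
        assert off < 0.01 * np.trace(cov)

    def test_degenerate_sphere_flagged(self):
        n = 41
        X, Y, Z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        ball = (X - 20) ** 2 + (Y - 20) ** 2 + (Z - 20) ** 2 <= 15**2
        with pytest.warns(UserWarning):
            _, frame = align_principal_axes(BinaryVolume(ball, 1.0))
        assert frame.degenerate
        assert np.allclose(frame.rotation, np.eye(3))


def _rot30():
    a = np.radians(30)
    return np.array(
        [[np.cos(a), np.sin(a), 0], [-np.sin(a), np.cos(a), 0], [0, 0, 1]]
    )


class TestTuberosity:
    @staticmethod
    def _wedge(flank_deg, height=12):
        nx, ny, nz = 120, 60, 9
        g = np.zeros((nx, ny, nz), bool)
        g[:, :21, :] = True
        slope = np.tan(np.radians(180.0 - flank_deg))
        x0, run = 40, height / np.tan(np.radians(180.0 - flank_deg))
        for x in range(nx):
            if x0 <= x <= x0 + 2 * run:
                h = slope * (x - x0) if x <= x0 + run else slope * (x0 + 2 * run - x)
                h = max(0.0, min(h, height))
                g[x, 21 : 21 + int(round(h)), :] = True
        return BinaryVolume(g, 1.0)

    def test_protrusion_beyond_angle_threshold_included(self):
        region = define_tuberosity(self._wedge(120.0), landmark_angle_deg=100.0)
        assert region.n_voxels > 0
        assert "empty" not in region.flags

    def test_protrusion_below_threshold_excluded(self):
        region = define_tuberosity(self._wedge(95.0), landmark_angle_deg=100.0)
        assert region.n_voxels == 0
        assert "empty" in region.flags

    def test_region_starts_where_angle_first_satisfied(self):
        region = define_tuberosity(self._wedge(140.0), landmark_angle_deg=100.0)
        xs = np.unique(np.argwhere(region.mask)[:, 0])
        assert xs.min() >= 40  # protrusion was built starting at x = 40


class TestVoiGrid:
    def test_span_arithmetic(self):
        assert voi_span_mm(7, 0.75, 0.375) == pytest.approx(3.0)
        assert voi_span_mm(3, 0.75, 0.375) == pytest.approx(1.5)
        assert voi_span_mm(1, 0.75, 0.375) == pytest.approx(0.75)

    def test_grid_marches_with_half_side_overlap(self):
        # 0.75 mm side at 5 µm voxels = 150 vox; region 4 mm long
        mask = np.ones((800, 160, 160), bool)
        region = RegionSpec("trabecular", mask, 5.0)
        vois = marching_voi_grid(region, 0.75, 0.375, direction=0)
        assert len(vois) >= 7
        sides = {v[0].stop - v[0].start for v in vois}
        assert sides == {150}
        starts = [v[0].start for v in vois]
        assert all(b - a == 75 for a, b in zip(starts, starts[1:]))
        # span of the first seven cubes: step*(n-1) + side = 600 vox = 3 mm
        assert (starts[6] + 150 - starts[0]) * 5.0 * 1e-3 == pytest.approx(3.0)

    def test_vois_stay_inside_region_mask(self):
        mask = np.zeros((400, 200, 200), bool)
        mask[:, 20:180, 20:180] = True
        region = RegionSpec("trabecular", mask, 5.0)
        vois = marching_voi_grid(region, 0.75, 0.375, direction=0)
        for v in vois:
            assert mask[v].all()

    def test_too_short_region_gives_empty_list(self):
        region = RegionSpec("trabecular", np.ones((100, 160, 160), bool), 5.0)
        assert marching_voi_grid(region, 0.75, 0.375, direction=0) == []

    def test_non_integral_side_rejected(self):
        region = RegionSpec("trabecular", np.ones((300, 300, 300), bool), 7.0)
        with pytest.raises(ValueError):
            marching_voi_grid(region, 0.75, 0.375, direction=0)
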