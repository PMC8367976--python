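"""Channel network: extraction, homotopic thinning, per-channel morphometry."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import euler_number

from enthemorph.channels import (
    channel_morphometry,
    channel_table,
    classify_aspect_ratio,
    extract_channels,
    global_channel_metrics,
    homotopic_thin,
    skeletonize_channels,
)
from enthemorph.orientation import axis_from_angles, orientation_heatmap
from enthemorph.phantoms import _carve_segment, make_tube_phantom
from enthemorph.volume import BinaryVolume

S26 = np.ones((3, 3, 3), dtype=bool)


def _pores(vol):
    return BinaryVolume(~vol.grid, vol.voxel_size)


class TestExtraction:
    def test_tree_survives_speckles_removed(self):
        # a connected 3-tube tree plus isolated 5-voxel speckles
        grid = np.ones((90, 90, 30), bool)
        _carve_segment(grid, np.array([15.0, 45.0, 15.0]), np.array([45.0, 45.0, 15.0]), 3.5)
        _carve_segment(grid, np.array([45.0, 45.0, 15.0]), np.array([70.0, 25.0, 15.0]), 3.0)
        _carve_segment(grid, np.array([45.0, 45.0, 15.0]), np.array([70.0, 65.0, 15.0]), 3.0)
        tree = (~grid).copy()
        rng = np.random.default_rng(0)
        n_speckles = 0
        while n_speckles < 50:
            p = rng.integers(3, np.array(grid.shape) - 4)
            if grid[p[0] - 1 : p[0] + 2, p[1] - 1 : p[1] + 2, p[2] - 1 : p[2] + 2].all():
                grid[p[0], p[1], p[2] : p[2] + 2] = False
                grid[p[0] + 1, p[1], p[2] : p[2] + 2] = False
                grid[p[0], p[1] + 1, p[2]] = False
                n_speckles += 1
        channels, flags = extract_channels(
            BinaryVolume(grid, 1.0), erosion_depth_um=0.0, min_area_px=20
        )
        assert "empty" not in flags
        speckles = (~grid) & ~tree
        assert not (channels.grid & speckles).any()  # every speckle removed
        assert not (channels.grid & ~tree).any()  # nothing outside the tree
        # the tree survives as one object; only sub-threshold tangent
        # cross-sections (a handful of voxels) may be despeckled away
        assert (channels.grid & tree).sum() >= 0.99 * tree.sum()
        assert ndimage.label(channels.grid, S26)[1] == 1

    def test_solid_block_flagged_empty(self):
        channels, flags = extract_channels(
            BinaryVolume(np.ones((40, 40, 40), bool), 1.0), erosion_depth_um=0.0
        )
        assert "empty" in flags
        assert not channels.grid.any()

    def test_erosion_depth_must_be_whole_voxels(self):
        vol = BinaryVolume(np.ones((30, 30, 30), bool), 3.0)
        with pytest.raises(ValueError, match="erosion depth"):
            extract_channels(vol, erosion_depth_um=125.0)

    def test_erosion_strips_surface_layer(self):
        # pore running inside the 125 µm surface layer disappears after erosion
        grid = np.ones((120, 120, 120), bool)
        _carve_segment(grid, np.array([20.0, 110.0, 60.0]), np.array([100.0, 110.0, 60.0]), 4.0)
        _carve_segment(grid, np.array([20.0, 60.0, 60.0]), np.array([100.0, 60.0, 60.0]), 4.0)
        channels, _ = extract_channels(
            BinaryVolume(grid, 12.5), erosion_depth_um=125.0, min_area_px=1
        )
        kept = np.argwhere(channels.grid)
        assert len(kept) > 0
        assert kept[:, 1].max() < 100  # only the deep tube survives


class TestThinning:
    def test_topology_preserved_on_tube_and_torus(self, single_tube, torus_pore):
        for vol in (_pores(single_tube[0]), torus_pore.invert()):
            mask = vol.grid
            skel = homotopic_thin(mask)
            n_before = ndimage.label(mask, structure=S26)[1]
            n_after = ndimage.label(skel, structure=S26)[1]
            assert n_before == n_after
            assert euler_number(mask, connectivity=3) == euler_number(skel, connectivity=3)

    def test_torus_skeleton_is_a_single_loop(self, torus_pore):
        g = skeletonize_channels(torus_pore.invert())
        assert euler_number(g.skeleton, connectivity=3) == 0  # one loop, one comp
        assert len(g.junction_centroids) == 0

    def test_skeleton_is_one_voxel_thin(self, single_tube):
        g = skeletonize_channels(_pores(single_tube[0]))
        # no 2x2x2 block of skeleton voxels survives thinning
        s = g.skeleton.astype(np.uint8)
        blocks = (
            s[:-1, :-1, :-1] + s[1:, :-1, :-1] + s[:-1, 1:, :-1] + s[:-1, :-1, 1:]
            + s[1:, 1:, :-1] + s[1:, :-1, 1:] + s[:-1, 1:, 1:] + s[1:, 1:, 1:]
        )
        assert blocks.max() < 8


class TestTopologyGraphs:
    def test_straight_tube_single_edge_full_length(self, single_tube):
        vol, truth = single_tube
        g = skeletonize_channels(_pores(vol))
        recs = channel_morphometry(g)
        assert len(recs) == 1
        assert recs[0].length_um == pytest.approx(60.0, abs=2.0)
        assert recs[0].connectivity == 0
        assert recs[0].orientation.theta == pytest.approx(90.0, abs=3.0)
        assert recs[0].orientation.phi == pytest.approx(0.0, abs=3.0) or recs[
            0
        ].orientation.phi == pytest.approx(180.0, abs=3.0)

    def test_y_junction_one_node_three_edges(self):
        grid = np.ones((70, 70, 30), bool)
        _carve_segment(grid, np.array([10.0, 35.0, 15.0]), np.array([35.0, 35.0, 15.0]), 3.5)
        _carve_segment(grid, np.array([35.0, 35.0, 15.0]), np.array([58.0, 18.0, 15.0]), 3.5)
        _carve_segment(grid, np.array([35.0, 35.0, 15.0]), np.array([58.0, 52.0, 15.0]), 3.5)
        g = skeletonize_channels(_pores(BinaryVolume(grid, 1.0)))
        recs = channel_morphometry(g)
        assert len(g.junction_centroids) == 1
        assert len(recs) == 3
        assert all(r.connectivity == 2 for r in recs)

    def test_star_of_four_gives_connectivity_three(self):
        grid = np.ones((80, 80, 30), bool)
        c = np.array([40.0, 40.0, 15.0])
        for ang in (30, 120, 210, 300):
            d = np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang)), 0.0])
            _carve_segment(grid, c, c + 30 * d, 3.0)
        g = skeletonize_channels(_pores(BinaryVolume(grid, 1.0)))
        recs = channel_morphometry(g)
        assert len(recs) == 4
        assert all(r.connectivity == 3 for r in recs)


class TestChannelRecords:
    def test_long_slender_tube_morphometry(self):
        vol, _ = make_tube_phantom(
            (200, 60, 60), voxel_size=1.25, tubes=[((1, 0, 0), 200.0, 15.0)], seed=0
        )
        r = channel_morphometry(skeletonize_channels(_pores(vol)))[0]
        assert r.length_um == pytest.approx(200.0, abs=5.0)
        assert r.diameter_um == pytest.approx(30.0, abs=2.5)
        assert r.aspect_class == "slender"

    @pytest.mark.parametrize(
        "rho, cls",
        [(1.5, "thick"), (1.0, "thick"), (0.5, "slender"), (0.10001, "slender"),
         (0.1, "extremely_slender"), (0.05, "extremely_slender")],
    )
    def test_aspect_class_boundaries(self, rho, cls):
        assert classify_aspect_ratio(rho) == cls

    def test_aspect_classes_partition_records(self, separated_tube_network):
        vol, _ = separated_tube_network
        recs = channel_morphometry(skeletonize_channels(_pores(vol)))
        table = channel_table(recs)
        assert set(table["class"]) <= {"thick", "slender", "extremely_slender"}
        for _, row in table.iterrows():
            assert classify_aspect_ratio(row["ch_rho"]) == row["class"]

    def test_orientation_recovery_under_5_degrees(self, separated_tube_network):
        """Mean absolute per-channel axis error < 5° at radii >= 4 voxels."""
        vol, truth = separated_tube_network
        g = skeletonize_channels(_pores(vol))
        recs = channel_morphometry(g)
        assert len(recs) == len(truth.objects)
        mids = (
            truth.objects[["x0", "y0", "z0"]].values
            + truth.objects[["x1", "y1", "z1"]].values
        ) / 2
        errs = []
        for r, e in zip(recs, g.edges):
            mid = e.path[len(e.path) // 2]
            i = int(np.argmin(np.linalg.norm(mids - mid, axis=1)))
            v = axis_from_angles(r.orientation.theta, r.orientation.phi)
            ta = truth.objects.iloc[i][["axis_x", "axis_y", "axis_z"]].values.astype(float)
            errs.append(np.degrees(np.arccos(np.clip(abs(v @ ta), 0, 1))))
        assert np.mean(errs) < 5.0

    def test_length_and_diameter_recovery(self, separated_tube_network):
        vol, truth = separated_tube_network
        g = skeletonize_channels(_pores(vol))
        recs = channel_morphometry(g)
        mids = (
            truth.objects[["x0", "y0", "z0"]].values
            + truth.objects[["x1", "y1", "z1"]].values
        ) / 2
        for r, e in zip(recs, g.edges):
            mid = e.path[len(e.path) // 2]
            i = int(np.argmin(np.linalg.norm(mids - mid, axis=1)))
            row = truth.objects.iloc[i]
            assert r.length_um == pytest.approx(row["length_um"], abs=6 * 2.5)
            assert r.diameter_um == pytest.approx(2 * row["radius_um"], abs=2.5)


class TestGlobalMetrics:
    def test_volume_fraction_and_diameter_recovery(self, separated_tube_network):
        vol, truth = separated_tube_network
        pores = _pores(vol)
        gm = global_channel_metrics(pores, tissue=None, n_directions=96, seed=0)
        true_vtv = 100.0 * (~vol.grid).mean()
        assert gm.ch_v_tv_pct == pytest.approx(true_vtv, abs=0.5)
        assert gm.ch_v_mm3 == pytest.approx(
            (~vol.grid).sum() * (2.5e-3) ** 3, rel=1e-9
        )
        mean_dm = 2 * truth.objects["radius_um"].mean()
        assert gm.ch_dm_um == pytest.approx(mean_dm, abs=5.0)

    def test_voxel_conservation_through_extraction(self):
        grid = np.ones((90, 90, 30), bool)
        _carve_segment(grid, np.array([15.0, 45.0, 15.0]), np.array([70.0, 45.0, 15.0]), 4.0)
        channels, _ = extract_channels(BinaryVolume(grid, 1.0), erosion_depth_um=0.0)
        per_slice = sum(int(channels.grid[:, :, z].sum()) for z in range(30))
        assert per_slice == int(channels.grid.sum())

    def test_parallel_vs_isotropic_anisotropy(self):
        par, _ = make_tube_phantom(
            (128, 128, 96), voxel_size=2.5, n_tubes=40, mean_axis=(1, 0.3, 0),
            axis_dispersion_deg=0.0, radius_um=(8, 15), length_um=(100, 200), seed=2,
        )
        iso, _ = make_tube_phantom(
            (128, 128, 96), voxel_size=2.5, n_tubes=40, axis_dispersion_deg=None,
            radius_um=(8, 15), length_um=(100, 200), seed=3,
        )
        gm_par = global_channel_metrics(_pores(par), tissue=None, n_directions=96, seed=0)
        gm_iso = global_channel_metrics(_pores(iso), tissue=None, n_directions=96, seed=0)
        assert gm_par.ch_da > 0.8
        assert gm_iso.ch_da < 0.3

    def test_empty_channel_phase_flagged(self):
        gm = global_channel_metrics(
            BinaryVolume(np.zeros((20, 20, 20), bool), 1.0)
        )
        assert gm.flags.get("empty")
        assert gm.ch_v_mm3 == 0.0


class TestHeatmaps:
    def test_identical_axes_fill_one_bin(self):
        hist, _, _, _ = orientation_heatmap([81.0] * 30, [11.0] * 30)
        assert (hist > 0).sum() == 1

    def test_isotropic_axes_no_dominant_bin(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(10000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        from enthemorph.orientation import canonical_axis

        angles = [canonical_axis(x) for x in v]
        thetas = [a.theta for a in angles]
        phis = [a.phi for a in angles]
        hist, et, ep, _ = orientation_heatmap(thetas, phis, bin_deg=20.0)
        # expected count per bin is proportional to the bin's solid angle
        t_lo = np.radians(et[:-1])[:, None]
        t_hi = np.radians(et[1:])[:, None]
        solid = (np.cos(t_lo) - np.cos(t_hi)) * np.ones((1, hist.shape[1]))
        expected = 10000 * solid / solid.sum()
        assert (hist[expected > 0] <= 3 * expected[expected > 0]).all()

    def test_phantom_peak_recovered_within_one_bin(self):
        vol, truth = make_tube_phantom(
            (128, 128, 96), voxel_size=2.5, n_tubes=30,
            mean_axis=tuple(axis_from_angles(80.0, 10.0)), axis_dispersion_deg=6.0,
            radius_um=(8, 14), length_um=(80, 160), min_separation_vox=2.0, seed=9,
        )
        recs = channel_morphometry(skeletonize_channels(_pores(vol)))
        hist, _, _, peak = orientation_heatmap(
            [r.orientation.theta for r in recs], [r.orientation.phi for r in recs]
        )
        assert abs(peak[0] - 80.0) <= 20.0
        assert abs(peak[1] - 10.0) <= 20.0
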