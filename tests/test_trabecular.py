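"""Trabecular morphometry: BV/TV, local thickness, MIL fabric, tuberosity."""

import numpy as np
import pytest

from enthemorph.fabric import (
    FabricTensor,
    degree_of_anisotropy,
    mil_fabric,
    preferred_orientation,
)
from enthemorph.orientation import axis_from_angles
from enthemorph.phantoms import make_trabecular_phantom, make_tube_phantom
from enthemorph.preprocess import RegionSpec, marching_voi_grid
from enthemorph.trabecular import (
    bone_volume_fraction,
    local_thickness,
    trabecular_metrics,
    tuberosity_metrics,
    voi_metrics_table,
)
from enthemorph.volume import BinaryVolume


class TestBoneVolumeFraction:
    def test_full_cube_and_half_slab(self):
        full = BinaryVolume(np.ones((10, 10, 10), bool), 1.0)
        assert bone_volume_fraction(full) == 100.0
        half = np.zeros((10, 10, 10), bool)
        half[:5] = True
        assert bone_volume_fraction(BinaryVolume(half, 1.0)) == 50.0

    def test_complement_sums_to_100(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(size=(20, 20, 20)) < 0.3
        b = BinaryVolume(g, 1.0)
        assert bone_volume_fraction(b) + bone_volume_fraction(b.invert()) == 100.0

    def test_rod_lattice_matches_analytic(self, rod_lattice):
        vol, truth = rod_lattice
        assert bone_volume_fraction(vol) == pytest.approx(
            truth.meta["bvtv_analytic_pct"], abs=2.0
        )


class TestLocalThickness:
    def test_slab_thickness_within_one_voxel(self):
        g = np.zeros((40, 40, 40), bool)
        g[:, 10:18, :] = True
        assert local_thickness(BinaryVolume(g, 1.0), "foreground") == pytest.approx(
            8.0, abs=1.0
        )

    def test_tube_pore_diameter_within_one_voxel(self):
        for r in (4.0, 5.0, 6.0):
            vol, _ = make_tube_phantom(
                (80, 44, 44), voxel_size=1.0, tubes=[((1, 0, 0), 50.0, r)], seed=0
            )
            dm = local_thickness(vol, "background")
            assert dm == pytest.approx(2 * r, abs=1.05)

    def test_separation_equals_thickness_of_inverse(self, single_tube):
        vol, _ = single_tube
        assert local_thickness(vol, "background") == local_thickness(
            vol.invert(), "foreground"
        )

    def test_empty_phase_rejected(self):
        full = BinaryVolume(np.ones((8, 8, 8), bool), 1.0)
        with pytest.raises(ValueError):
            local_thickness(full, "background")


class TestFabric:
    def test_plate_lattice_largest_mil_in_plane(self, plate_lattice):
        vol, _ = plate_lattice
        f = mil_fabric(vol, n_directions=128, seed=0)
        # smallest eigenvalue of the MIL^-2 form = longest intercepts:
        # for plates normal to z that direction lies in the XY plane
        v = f.eigenvectors[:, 2]
        assert abs(v[2]) < np.sin(np.radians(5.0))

    def test_cubic_lattice_eigenvalue_spread_small(self, rod_lattice):
        vol, _ = rod_lattice
        f = mil_fabric(vol, n_directions=128, seed=0)
        assert (f.eigenvalues[0] - f.eigenvalues[2]) / f.eigenvalues[0] < 0.1

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError):
            mil_fabric(BinaryVolume(np.ones((16, 16, 16), bool), 1.0))

    def test_da_rotation_invariance_on_plate_lattices(self):
        """DA is a rotational invariant: lattices built at 5 random
        orientations give the same DA within 0.05."""
        rng = np.random.default_rng(7)
        das = []
        for k in range(5):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            vol, _ = make_trabecular_phantom(
                (120, 120, 120), voxel_size=5.0, mode="plates",
                thickness_um=100.0, spacing_um=100.0, fabric_axis=tuple(v), seed=k,
            )
            das.append(degree_of_anisotropy(mil_fabric(vol, n_directions=128, seed=k)))
        assert max(das) - min(das) < 0.05


class TestDegreeOfAnisotropy:
    def test_isotropic_limit(self):
        f = FabricTensor(np.array([1.0, 1.0, 1.0]), np.eye(3), 512)
        assert degree_of_anisotropy(f) == 0.0

    def test_fully_anisotropic_limit(self):
        f = FabricTensor(np.array([1.0, 0.5, 0.0]), np.eye(3), 512)
        assert degree_of_anisotropy(f) == 1.0

    def test_intermediate(self):
        f = FabricTensor(np.array([2.0, 1.5, 1.0]), np.eye(3), 512)
        assert degree_of_anisotropy(f) == pytest.approx(0.5)


class TestPreferredOrientation:
    def test_plates_normal_to_z_give_in_plane_theta_90(self, plate_lattice):
        vol, _ = plate_lattice
        f = mil_fabric(vol, n_directions=128, seed=0)
        axis, reliable = preferred_orientation(f)
        assert reliable
        assert axis.theta == pytest.approx(90.0, abs=5.0)

    def test_x_axis_eigenvector(self):
        f = FabricTensor(np.array([2.0, 1.0, 0.5]),
                         np.array([[0, 0, 1.0], [0, 1.0, 0], [1.0, 0, 0]]).T, 512)
        axis, _ = preferred_orientation(f)
        assert axis.theta == pytest.approx(90.0)
        assert axis.phi == pytest.approx(0.0)

    def test_near_isotropic_flagged_unreliable(self, rod_lattice):
        vol, _ = rod_lattice
        f = mil_fabric(vol, n_directions=128, seed=0)
        _, reliable = preferred_orientation(f)
        assert not reliable

    def test_tube_fabric_axis_at_minus_19p5_recovered(self):
        """Pore fabric of parallel tubes at ϕ = -19.5° (=160.5° canonical)."""
        phi0 = 160.5
        ax = axis_from_angles(90.0, phi0)
        vol, _ = make_tube_phantom(
            (128, 128, 96), voxel_size=2.5, n_tubes=40, mean_axis=tuple(ax),
            axis_dispersion_deg=0.0, radius_um=(8, 15), length_um=(100, 200), seed=2,
        )
        pores = BinaryVolume(~vol.grid, 2.5)
        f = mil_fabric(pores, n_directions=128, seed=0)
        axis, reliable = preferred_orientation(f)
        assert reliable
        rec = axis_from_angles(axis.theta, axis.phi)
        ang = np.degrees(np.arccos(np.clip(abs(rec @ ax), 0, 1)))
        assert ang < 5.0


class TestVoiTable:
    def test_adjacent_voi_bvtv_varies_smoothly_on_homogeneous_lattice(self):
        vol, _ = make_trabecular_phantom(
            (300, 160, 160), voxel_size=5.0, mode="plates",
            thickness_um=100.0, spacing_um=100.0, fabric_axis=(0, 0, 1), seed=0,
        )
        region = RegionSpec("trabecular", np.ones(vol.shape, bool), 5.0)
        vois = marching_voi_grid(region, 0.75, 0.375, direction=0)
        assert len(vois) >= 3
        bv = [bone_volume_fraction(BinaryVolume(vol.grid[box], 5.0)) for box in vois]
        diffs = np.abs(np.diff(bv))
        assert (diffs < 10.0).all()

    def test_voi_metrics_table_columns_and_positions(self):
        # VOI side (75 vox) is an exact multiple of the lattice period
        # (75 µm plates + 50 µm gaps = 25 vox), so BV/TV is exactly 60 %
        vol, _ = make_trabecular_phantom(
            (160, 80, 80), voxel_size=5.0, mode="plates",
            thickness_um=75.0, spacing_um=50.0, fabric_axis=(0, 0, 1),
            phase_offset_um=100.0, seed=0,
        )
        region = RegionSpec("trabecular", np.ones(vol.shape, bool), 5.0)
        vois = marching_voi_grid(region, 0.375, 0.125, direction=0)
        table = voi_metrics_table(vol, vois, n_directions=32, seed=0)
        assert list(table.columns) == [
            "voi", "position_mm", "bvtv_pct", "tb_th_um", "tb_sp_um",
            "da", "pref_theta_deg", "pref_phi_deg",
        ]
        assert len(table) == len(vois)
        assert table["position_mm"].is_monotonic_increasing
        assert np.allclose(table["bvtv_pct"], 60.0, atol=0.5)

    def test_graded_spacing_recovers_bvtv_slope(self):
        """Linearly graded plate spacing: the fitted BV/TV-vs-x slope has the
        constructed sign and magnitude within 25 %."""
        vol, _ = make_trabecular_phantom(
            (450, 160, 160), voxel_size=5.0, mode="plates",
            thickness_um=100.0, spacing_um=60.0, spacing_end_um=150.0,
            fabric_axis=(1, 0, 0), seed=0,
        )
        region = RegionSpec("trabecular", np.ones(vol.shape, bool), 5.0)
        vois = marching_voi_grid(region, 0.75, 0.375, direction=0)
        rows = []
        for box in vois:
            sub = BinaryVolume(vol.grid[box], 5.0)
            pos = (box[0].start + box[0].stop) / 2 * 5.0 * 1e-3
            rows.append((pos, bone_volume_fraction(sub)))
        pos, bv = np.array(rows).T
        slope = np.polyfit(pos, bv, 1)[0]
        # constructed: fraction falls from 100/160 to 100/250 over 2.25 mm
        expected = (100 / 250 - 100 / 160) * 100 / (450 * 5e-3)
        assert np.sign(slope) == np.sign(expected)
        assert slope == pytest.approx(expected, rel=0.25)


class TestTuberosityMetrics:
    @staticmethod
    def _cone_region(phi_deg=21.0, h=60, r_base=25):
        """Solid cone with axis in the XY plane at azimuth phi_deg."""
        n = 120
        X, Y, Z = np.meshgrid(*[np.arange(n, dtype=float)] * 3, indexing="ij")
        apex = np.array([30.0, 30.0, 60.0])
        ax = axis_from_angles(90.0, phi_deg)
        P = np.stack([X, Y, Z], -1) - apex
        t = P @ ax
        rad = np.linalg.norm(P - t[..., None] * ax[None, None, None, :], axis=-1)
        cone = (t >= 0) & (t <= h) & (rad <= r_base * t / h)
        return cone, h, r_base

    def test_cone_volume_porosity_and_azimuth(self):
        cone, h, r_base = self._cone_region()
        vs = 10.0  # µm
        region = RegionSpec("tuberosity", cone, vs)
        analytic_mm3 = (np.pi * r_base**2 * h / 3.0) * (vs * 1e-3) ** 3
        # high-resolution volume with 15 % of cone voxels carved as pores
        rng = np.random.default_rng(0)
        grid = np.ones_like(cone)
        pores = cone & (rng.uniform(size=cone.shape) < 0.15)
        grid[pores] = False
        m = tuberosity_metrics(
            region,
            b_low=BinaryVolume(cone, vs),
            b_high=BinaryVolume(grid, vs),
        )
        assert m.t_tv_mm3 == pytest.approx(analytic_mm3, rel=0.03)
        assert m.t_po_pct == pytest.approx(15.0, abs=1.0)
        assert m.t_phi_deg == pytest.approx(21.0, abs=2.0)

    def test_empty_region_rejected(self):
        region = RegionSpec("tuberosity", np.zeros((10, 10, 10), bool), 1.0)
        with pytest.raises(ValueError):
            tuberosity_metrics(region, BinaryVolume(np.ones((10, 10, 10), bool), 1.0))


def test_trabecular_metrics_bundle(plate_lattice):
    vol, truth = plate_lattice
    m = trabecular_metrics(vol, n_directions=64, seed=0)
    assert m.bvtv_pct == pytest.approx(truth.meta["bvtv_analytic_pct"], abs=2.0)
    assert m.tb_th_um == pytest.approx(100.0, abs=5.0)
    assert m.tb_sp_um == pytest.approx(100.0, abs=5.0)
    assert m.da > 0.7
    assert 0 <= m.bvtv_pct <= 100 and m.tb_th_um > 0 and m.tb_sp_um > 0
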