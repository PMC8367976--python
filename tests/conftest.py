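"""Shared phantom fixtures (session-scoped: generation is the expensive part)."""

from __future__ import annotations

import numpy as np
import pytest

from enthemorph.phantoms import make_lacuna_phantom, make_trabecular_phantom, make_tube_phantom
from enthemorph.volume import BinaryVolume


@pytest.fixture(scope="session")
def single_tube():
    """One straight tube along +x, radius 4 voxels, in a solid plate."""
    vol, truth = make_tube_phantom(
        (100, 40, 40), voxel_size=1.0, tubes=[((1, 0, 0), 60.0, 4.0)], seed=0
    )
    return vol, truth


@pytest.fixture(scope="session")
def separated_tube_network():
    """25 non-intersecting tubes with dispersed axes and per-tube truth."""
    vol, truth = make_tube_phantom(
        (128, 128, 96),
        voxel_size=2.5,
        n_tubes=25,
        mean_axis=(1.0, 0.35, 0.2),
        axis_dispersion_deg=25.0,
        radius_um=(10.0, 20.0),
        length_um=(100.0, 180.0),
        min_separation_vox=2.0,
        seed=5,
    )
    return vol, truth


@pytest.fixture(scope="session")
def plate_lattice():
    """Parallel-plate lattice, 100 µm plates / 100 µm gaps, normal along z.

    Phase-shifted so no plate touches a volume face (face-cut plates would
    read as continuing beyond the volume in thickness analyses).
    """
    return make_trabecular_phantom(
        (120, 120, 120), voxel_size=5.0, mode="plates",
        thickness_um=100.0, spacing_um=100.0, fabric_axis=(0, 0, 1),
        phase_offset_um=150.0, seed=0,
    )


@pytest.fixture(scope="session")
def rod_lattice():
    """Cubic-symmetric rod lattice (isotropic fabric)."""
    return make_trabecular_phantom(
        (120, 120, 120), voxel_size=5.0, mode="rods",
        thickness_um=100.0, spacing_um=100.0, seed=0,
    )


@pytest.fixture(scope="session")
def aligned_lacunae():
    """Columnar lacuna aggregates aligned at (θ, ϕ) = (80°, 31°)."""
    return make_lacuna_phantom(
        (200, 200, 140), n_lacunae=50, voxel_size=1.25,
        volume_range_um3=(4000.0, 12000.0), axis_ratio=3.5,
        orientation_mode="aligned", mean_angles_deg=(80.0, 31.0),
        arrangement="columns", aggregate_size=5, seed=3,
    )


@pytest.fixture(scope="session")
def isotropic_lacunae():
    """Clustered lacuna aggregates with isotropic axes."""
    return make_lacuna_phantom(
        (200, 200, 140), n_lacunae=50, voxel_size=1.25,
        volume_range_um3=(4000.0, 12000.0), axis_ratio=3.5,
        orientation_mode="isotropic", arrangement="clusters",
        aggregate_size=5, seed=4,
    )


@pytest.fixture(scope="session")
def torus_pore():
    """A solid block with a torus-shaped pore (one loop, one component)."""
    n = 64
    X, Y, Z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    c = n / 2
    torus = (np.sqrt((X - c) ** 2 + (Y - c) ** 2) - 18.0) ** 2 + (Z - c) ** 2 <= 36.0
    return BinaryVolume(~torus, 1.0)
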