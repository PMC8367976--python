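"""Voxel-volume containers shared by all morphometry stages.

Axis convention (fixed after inertia alignment): index 0 = x (cranio-caudal),
index 1 = y (dorso-plantar), index 2 = z (medio-lateral).  The sagittal plane
is the XY plane.  Voxel size is isotropic and carried in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelVolume", "BinaryVolume"]


def _check_voxel_size(voxel_size: float) -> float:
    voxel_size = float(voxel_size)
    if not voxel_size > 0:
        raise ValueError(f"voxel_size must be positive, got {voxel_size}")
    return voxel_size


@dataclass
class VoxelVolume:
    """A 3D scalar grid with isotropic voxel size in micrometres."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]


@dataclass
class BinaryVolume:
    """A segmented 3D volume; foreground means mineralized tissue."""

    grid: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def invert(self) -> "BinaryVolume":
        return BinaryVolume(~self.grid, self.voxel_size)

    @property
    def volume_um3(self) -> float:
        """Foreground volume in µm³."""
        return float(self.grid.sum()) * self.voxel_size**3
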