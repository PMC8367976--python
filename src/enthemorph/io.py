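"""Volume and table I/O: multi-page TIFF, HDF5 with voxel-size metadata, CSV.

Grids use the package axis convention (x, y, z); TIFF stacks store one page
per z-slice, so volumes are transposed to (z, y, x) on write and back on
read.  HDF5 volumes carry the voxel size in a ``voxel_size_um`` attribute,
which takes precedence over a configured value.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .volume import VoxelVolume

__all__ = ["read_volume", "write_volume", "read_table", "write_table"]


def write_volume(v: VoxelVolume, path: str | Path, dtype=None) -> None:
    path = Path(path)
    grid = np.asarray(v.grid)
    if dtype is not None:
        grid = grid.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        if grid.dtype == bool:
            grid = grid.astype(np.uint8) * 255
        tifffile.imwrite(path, np.transpose(grid, (2, 1, 0)))
    elif path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=grid)
            ds.attrs["voxel_size_um"] = v.voxel_size
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    """Read a TIFF stack or HDF5 volume.

    TIFF carries no voxel-size metadata, so ``voxel_size`` is required; an
    HDF5 ``voxel_size_um`` attribute is honoured over the argument.
    Anisotropic voxel metadata is rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        if voxel_size is None:
            raise ValueError("TIFF stacks carry no voxel size: pass voxel_size")
        grid = np.transpose(tifffile.imread(path), (2, 1, 0))
        return VoxelVolume(grid, voxel_size)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["volume"]
            vs = ds.attrs.get("voxel_size_um", voxel_size)
            grid = ds[()]
        if vs is None:
            raise ValueError("no voxel_size_um attribute and no voxel_size given")
        vs_arr = np.atleast_1d(np.asarray(vs, dtype=float))
        if vs_arr.size > 1 and not np.allclose(vs_arr, vs_arr[0]):
            raise ValueError("anisotropic voxel sizes are not supported")
        return VoxelVolume(grid, float(vs_arr[0]))
    raise ValueError(f"unsupported volume format: {path.suffix}")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(records).to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
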