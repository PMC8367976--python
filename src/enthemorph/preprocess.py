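"""Filtering, segmentation, inertia alignment and region/VOI definition.

Every volume passes through the same preparation before morphometry: a light
3D Gaussian filter (3x3x3 support, sigma 0.65 voxels by default), a single
global Otsu threshold, alignment along the principal axes of inertia of the
segmented bone, and definition of the regions and cubic volumes of interest
used by the spatially resolved analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BinaryVolume, VoxelVolume

__all__ = [
    "InertiaFrame",
    "RegionSpec",
    "gaussian_smooth",
    "otsu_threshold",
    "binarize",
    "align_principal_axes",
    "define_tuberosity",
    "separate_compartments",
    "marching_voi_grid",
    "voi_span_mm",
]


@dataclass
class InertiaFrame:
    """Rigid frame mapping a volume onto its principal axes of inertia."""

    rotation: np.ndarray  # 3x3, rows are the new axes in old coordinates
    centroid: np.ndarray  # voxel coordinates in the input volume
    degenerate: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        self.rotation = R


@dataclass
class RegionSpec:
    """A named analysis region: a voxel mask plus bookkeeping flags."""

    label: str
    mask: np.ndarray
    voxel_size: float
    flags: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * (self.voxel_size * 1e-3) ** 3

    def bounding_box(self) -> tuple[slice, ...]:
        objs = ndimage.find_objects(self.mask.astype(np.uint8))
        if not objs or objs[0] is None:
            raise ValueError(f"region {self.label!r} is empty")
        return objs[0]


def gaussian_smooth(
    v: VoxelVolume,
    sigma: float = 0.65,
    support_radius: int = 1,
    mode: str = "reflect",
) -> VoxelVolume:
    """3D Gaussian filter with a small square kernel.

    ``sigma`` is in voxels; ``support_radius`` = 1 gives the default 3x3x3
    support.  Reflective padding keeps the mean gray value at the faces so the
    subsequent global threshold is not biased by darkened borders.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    out = ndimage.gaussian_filter(
        np.asarray(v.grid, dtype=float), sigma=sigma, radius=support_radius, mode=mode
    )
    return VoxelVolume(out, v.voxel_size)


def otsu_threshold(v: VoxelVolume, nbins: int = 256) -> float:
    """Global threshold maximizing between-class variance (Otsu).

    The maximization is exhaustive over candidate gray levels (every distinct
    value, or ``nbins`` quantized levels for near-continuous data), so the
    returned threshold t satisfies: the classification ``gray > t`` attains
    the maximal between-class variance among all candidate splits, with the
    lowest such t on ties.  Voxels equal to the threshold are background.
    """
    vals = np.asarray(v.grid, dtype=float).ravel()
    levels = np.unique(vals)
    if levels.size < 2:
        raise ValueError("Otsu threshold undefined on a constant volume")
    if levels.size > nbins:
        # quantize to nbins levels; candidates are the level representatives
        edges = np.linspace(vals.min(), vals.max(), nbins + 1)
        idx = np.clip(np.digitize(vals, edges[1:-1]), 0, nbins - 1)
        levels = 0.5 * (edges[:-1] + edges[1:])
        counts = np.bincount(idx, minlength=nbins).astype(float)
        sums = np.bincount(idx, weights=vals, minlength=nbins)
    else:
        idx = np.searchsorted(levels, vals)
        counts = np.bincount(idx, minlength=levels.size).astype(float)
        sums = np.bincount(idx, weights=vals, minlength=levels.size)
    w0 = np.cumsum(counts)[:-1]
    s0 = np.cumsum(sums)[:-1]
    w1 = counts.sum() - w0
    s1 = sums.sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    var = np.zeros_like(w0)
    var[valid] = (
        w0[valid] * w1[valid] * (s0[valid] / w0[valid] - s1[valid] / w1[valid]) ** 2
    )
    return float(levels[int(np.argmax(var))])


def binarize(v: VoxelVolume, threshold: float | None = None) -> BinaryVolume:
    """Segment mineralized tissue with a global threshold (Otsu by default)."""
    if threshold is None:
        threshold = otsu_threshold(v)
    return BinaryVolume(np.asarray(v.grid) > threshold, v.voxel_size)


def _principal_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]  # largest second moment = long axis first
    evals = evals[order]
    evecs = evecs[:, order]
    spread = (evals[0] - evals[2]) / max(evals[0], 1e-12)
    degenerate = spread < 1e-3
    if degenerate:
        return np.eye(3), centroid, True
    # sign convention: largest-magnitude component of each axis positive,
    # then flip z to keep the frame right-handed
    for k in range(3):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] *= -1
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] *= -1
    return evecs.T, centroid, False


def align_principal_axes(b: BinaryVolume) -> tuple[BinaryVolume, InertiaFrame]:
    """Rotate a segmented volume onto its principal axes of inertia.

    The axis of the smallest inertia moment (largest second moment of the
    foreground, i.e. the long axis) maps to x.  Binary data are resampled with
    nearest-neighbour interpolation to preserve binarity.  A near-spherical
    inertia tensor yields the identity rotation with ``degenerate=True``.
    """
    coords = np.argwhere(b.grid)
    if coords.size == 0:
        raise ValueError("foreground is empty")
    R, centroid, degenerate = _principal_frame(coords.astype(float))
    if degenerate:
        warnings.warn("degenerate inertia tensor: returning identity rotation")
        return BinaryVolume(b.grid.copy(), b.voxel_size), InertiaFrame(
            np.eye(3), centroid, degenerate=True
        )
    out_center = (np.array(b.grid.shape) - 1) / 2.0
    # output->input map: x_in = R^T (x_out - out_center) + centroid
    aligned = ndimage.affine_transform(
        b.grid.astype(np.uint8),
        R.T,
        offset=centroid - R.T @ out_center,
        order=0,
        mode="constant",
        cval=0,
        output_shape=b.grid.shape,
    ).astype(bool)
    return BinaryVolume(aligned, b.voxel_size), InertiaFrame(R, centroid)


def define_tuberosity(
    b: BinaryVolume,
    landmark_angle_deg: float = 100.0,
    min_height_vox: int = 2,
) -> RegionSpec:
    """Delimit the bony protrusion (tuberosity) on the plantar surface.

    Works on an aligned volume with x cranio-caudal and +y plantar-pointing.
    Per sagittal slice the plantar surface height is extracted; the protrusion
    is the surface rise of at least ``min_height_vox`` voxels above the fitted
    flat contour, starting where the flank makes an angle of at least
    ``landmark_angle_deg`` with the flat periosteal surface (180° = flat,
    90° = vertical cliff) and ending where no protrusion is evident (height
    falls back under ``min_height_vox``).

    Returns a region whose mask covers the protruding voxels; an empty region
    is flagged when no slice satisfies the angle criterion.
    """
    grid = b.grid
    nx, ny, nz = grid.shape
    mask = np.zeros_like(grid)
    any_found = False
    for z in range(nz):
        sl = grid[:, :, z]
        cols = sl.any(axis=1)
        if not cols.any():
            continue
        ys = np.where(sl.any(axis=1)[:, None] & sl, np.arange(ny)[None, :], -1)
        h = ys.max(axis=1).astype(float)  # plantar surface height per x
        h[~cols] = np.nan
        valid = ~np.isnan(h)
        if valid.sum() < 5:
            continue
        baseline = float(np.nanmedian(h))
        rise = h - baseline
        prot = valid & (rise >= min_height_vox)
        if not prot.any():
            continue
        # flank angle at the protrusion onset: slope of the ascending flank
        xs = np.where(prot)[0]
        x_start = xs.min()
        x_peak = xs[np.argmax(rise[xs])]
        if x_peak <= x_start:
            slope = np.inf
        else:
            slope = (h[x_peak] - baseline) / (x_peak - x_start)
        angle = 180.0 - np.degrees(np.arctan(slope))
        if angle < landmark_angle_deg:
            continue
        any_found = True
        for x in xs:
            y_top = int(h[x])
            y_base = int(np.floor(baseline))
            mask[x, y_base + 1 : y_top + 1, z] |= grid[x, y_base + 1 : y_top + 1, z]
    flags = {} if any_found else {"empty": "no slice satisfied the angle criterion"}
    return RegionSpec("tuberosity", mask, b.voxel_size, flags=flags)


def separate_compartments(
    b: BinaryVolume,
    despeckle_min_vox: int = 64,
    closing_radius_vox: float = 5.0,
    erosion_radius_vox: float = 8.0,
) -> tuple[RegionSpec, RegionSpec]:
    """Split bone into cortical-shell and trabecular compartments.

    A parameterized morphological recipe: remove small speckles, close the
    bone envelope (filling the inter-trabecular spaces), then erode the
    envelope by the expected cortical-shell thickness; bone inside the eroded
    envelope is trabecular, the rest is the cortical shell.  The radii are
    exposed because the appropriate values depend on specimen scale.
    """
    grid = b.grid
    labels, n = ndimage.label(grid, structure=np.ones((3, 3, 3), bool))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        small = np.where(sizes < despeckle_min_vox)[0] + 1
        if small.size:
            grid = grid & ~np.isin(labels, small)
    # closing by r: dilate (EDT of background <= r) then erode back
    dilated = ndimage.distance_transform_edt(~grid) <= closing_radius_vox
    envelope = ndimage.distance_transform_edt(dilated) > closing_radius_vox
    envelope |= grid  # never lose actual bone from the envelope
    core = ndimage.distance_transform_edt(envelope) > erosion_radius_vox
    trabecular = grid & core
    cortical = grid & ~core
    return (
        RegionSpec("cortical", cortical, b.voxel_size),
        RegionSpec("trabecular", trabecular, b.voxel_size),
    )


def voi_span_mm(n_cubes: int, side_mm: float = 0.75, step_mm: float = 0.375) -> float:
    """Total length covered by ``n_cubes`` marching cubes: step*(n-1) + side."""
    if n_cubes < 1:
        raise ValueError("need at least one cube")
    return step_mm * (n_cubes - 1) + side_mm


def marching_voi_grid(
    region: RegionSpec,
    side_mm: float = 0.75,
    step_mm: float = 0.375,
    direction: int = 0,
    require_inside_mask: bool = True,
) -> list[tuple[slice, slice, slice]]:
    """Ordered list of cubic VOIs marching along one axis of a region.

    Cube side and step must be whole numbers of voxels.  Cubes are centred on
    the region's bounding box in the two transverse directions and advance
    along ``direction`` from the low edge; cubes that would cross the region
    boundary (or, when ``require_inside_mask``, contain non-region voxels) are
    not emitted.
    """
    vs_mm = region.voxel_size * 1e-3
    side = side_mm / vs_mm
    step = step_mm / vs_mm
    if abs(side - round(side)) > 1e-6 or abs(step - round(step)) > 1e-6:
        raise ValueError("side and step must be whole numbers of voxels")
    side = int(round(side))
    step = int(round(step))
    bbox = region.bounding_box()
    starts = [s.start for s in bbox]
    stops = [s.stop for s in bbox]
    if any(stops[a] - starts[a] < side for a in range(3)):
        return []
    vois: list[tuple[slice, slice, slice]] = []
    pos = starts[direction]
    while pos + side <= stops[direction]:
        idx: list[slice] = []
        for a in range(3):
            if a == direction:
                idx.append(slice(pos, pos + side))
            else:
                center = (starts[a] + stops[a]) // 2
                lo = center - side // 2
                idx.append(slice(lo, lo + side))
        box = tuple(idx)
        ok = all(0 <= box[a].start and box[a].stop <= region.mask.shape[a] for a in range(3))
        if ok and require_inside_mask:
            ok = bool(region.mask[box].all())
        if ok:
            vois.append(box)  # type: ignore[arg-type]
        pos += step
    return vois
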