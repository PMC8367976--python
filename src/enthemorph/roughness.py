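"""Two-dimensional interface roughness on sagittal cross-sections.

Within a rectangular mask the mineralization-front contour is extracted from
the segmented image, a 5th-order polynomial reference line captures the
overall surface shape without absorbing local roughness, surface heights are
shortest (Euclidean) distances from the contour points to the reference
curve, and roughness is reported as the root mean square height Pq.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RoughnessMask",
    "RoughnessResult",
    "extract_contour",
    "fit_reference",
    "rms_roughness",
    "measure_roughness",
    "threshold_sensitivity",
    "mask_schedule",
]


@dataclass
class RoughnessMask:
    """Rectangular mask in slice coordinates (rows x cols, pixels)."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int
    slice_index: int = 0

    def crop(self, image: np.ndarray) -> np.ndarray:
        sub = image[self.row0 : self.row0 + self.n_rows, self.col0 : self.col0 + self.n_cols]
        if sub.shape != (self.n_rows, self.n_cols):
            raise ValueError("mask does not fit inside the slice")
        return sub


@dataclass
class RoughnessResult:
    pq_um: float
    reference_coeffs: np.ndarray
    n_points: int
    excluded: bool = False
    reason: str = ""
    meta: dict = field(default_factory=dict)


def extract_contour(
    slice2d: np.ndarray,
    mask: RoughnessMask | None = None,
    max_multivalued_frac: float = 0.05,
) -> tuple[np.ndarray, bool, str]:
    """Ordered boundary points of the foreground within a mask.

    The image convention is foreground (mineralized) below the interface
    (larger row index); for each column the topmost foreground transition is
    the contour point.  Columns whose profile is multi-valued (more than one
    foreground run, e.g. a blood-vessel opening) are tolerated up to
    ``max_multivalued_frac``; beyond that the mask is marked excluded.

    Returns (points, excluded, reason) with points as (x=column, y=row) pairs.
    """
    sub = mask.crop(np.asarray(slice2d, dtype=bool)) if mask is not None else np.asarray(slice2d, bool)
    n_rows, n_cols = sub.shape
    fg_any = sub.any(axis=0)
    if not fg_any.any() or sub.all():
        return np.empty((0, 2)), True, "mask does not intersect a boundary"
    # runs of foreground per column
    padded = np.zeros((n_rows + 2, n_cols), dtype=bool)
    padded[1:-1] = sub
    starts = padded[1:] & ~padded[:-1]
    n_runs = starts.sum(axis=0)
    multi = (n_runs > 1).sum()
    if multi > max_multivalued_frac * n_cols:
        return np.empty((0, 2)), True, "boundary multi-valued (pore opening in mask)"
    top = np.argmax(sub, axis=0).astype(float)  # first foreground row per column
    valid = fg_any & (n_runs >= 1)
    xs = np.nonzero(valid)[0]
    pts = np.stack([xs.astype(float), top[xs]], axis=1)
    return pts, False, ""


def fit_reference(points: np.ndarray, order: int = 5) -> np.polynomial.Polynomial:
    """Least-squares polynomial reference line of the contour (degree 5)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 2 * (order + 1):
        raise ValueError(f"need at least {2 * (order + 1)} contour points")
    x, y = points[:, 0], points[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate contour: zero extent along the interface")
    return np.polynomial.Polynomial.fit(x, y, deg=order)


def rms_roughness(
    points: np.ndarray,
    reference: np.polynomial.Polynomial,
    voxel_size: float = 1.0,
    curve_step: float = 0.1,
) -> float:
    """Root mean square height Pq (µm) from shortest Euclidean distances.

    The reference curve is densely sampled (``curve_step`` pixels along x)
    and each contour point's height is its distance to the nearest curve
    sample; Pq is the RMS of those heights.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("no contour points")
    x = points[:, 0]
    xs = np.arange(x.min() - 2, x.max() + 2 + curve_step, curve_step)
    curve = np.stack([xs, reference(xs)], axis=1)
    tree = cKDTree(curve)
    d, _ = tree.query(points)
    return float(np.sqrt(np.mean(d**2))) * voxel_size


def measure_roughness(
    slice2d: np.ndarray,
    mask: RoughnessMask | None = None,
    voxel_size: float = 1.25,
    order: int = 5,
) -> RoughnessResult:
    """Full per-mask measurement: contour, reference fit and Pq."""
    pts, excluded, reason = extract_contour(slice2d, mask)
    if excluded:
        return RoughnessResult(float("nan"), np.full(order + 1, np.nan), 0, True, reason)
    ref = fit_reference(pts, order=order)
    pq = rms_roughness(pts, ref, voxel_size=voxel_size)
    return RoughnessResult(pq, ref.convert().coef, len(pts), False, "")


def threshold_sensitivity(
    gray_slice: np.ndarray,
    base_threshold: float,
    offsets_frac,
    mask: RoughnessMask | None = None,
    voxel_size: float = 1.25,
    order: int = 5,
) -> pd.DataFrame:
    """Pq re-measured across relative threshold offsets.

    Each offset rescales the segmentation threshold by (1 + offset); offsets
    that collapse one of the phases are skipped and logged in the table.
    """
    rows = []
    gray = np.asarray(gray_slice, dtype=float)
    for off in offsets_frac:
        thr = base_threshold * (1.0 + off)
        seg = gray > thr
        if not seg.any() or seg.all():
            rows.append({"offset": off, "pq_um": np.nan, "skipped": True, "reason": "phase collapsed"})
            continue
        res = measure_roughness(seg, mask, voxel_size=voxel_size, order=order)
        rows.append(
            {"offset": off, "pq_um": res.pq_um, "skipped": res.excluded, "reason": res.reason}
        )
    return pd.DataFrame(rows)


def mask_schedule(
    n_samples: int = 5,
    n_sections: int = 10,
    regions: tuple = ("tuberosity", "periosteal", "cortical"),
    section_spacing_um: float = 30.0,
    voxel_size: float = 1.25,
) -> pd.DataFrame:
    """Bookkeeping table of the per-sample roughness mask locations.

    The study design measures ``n_sections`` sagittal sections per sample,
    about 30 µm apart, in each region: 5 samples x 10 sections x 3 regions
    gives 150 mask locations.
    """
    step = int(round(section_spacing_um / voxel_size))
    rows = []
    for s in range(n_samples):
        for region in regions:
            for k in range(n_sections):
                rows.append(
                    {
                        "sample": s,
                        "region": region,
                        "section": k,
                        "slice_index": k * step,
                    }
                )
    return pd.DataFrame(rows)
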