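"""Spherical orientation convention shared by channels, lacunae and fabric.

Orientations of undirected microstructural axes (channels, lacuna long axes,
trabecular fabric) are expressed as a polar angle θ (from the +z, medio-lateral
axis) and an azimuthal angle ϕ (angle of the XY-plane projection, measured from
+x).  Because an axis and its negation are the same physical orientation, every
vector is mapped onto an arbitrary half sphere by requiring 0° ≤ ϕ < 180°; a
vector and its antipode then produce identical angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationAxis",
    "canonical_axis",
    "axis_from_angles",
    "orientation_heatmap",
    "phi_frequency",
]


@dataclass(frozen=True)
class OrientationAxis:
    """Canonical axis orientation: θ polar from +z, ϕ azimuth in [0°, 180°)."""

    theta: float
    phi: float
    phi_defined: bool = True

    def as_tuple(self) -> tuple[float, float]:
        return (self.theta, self.phi)


def canonical_axis(v, atol: float = 1e-12) -> OrientationAxis:
    """Map a direction vector onto the canonical half sphere.

    The vector is flipped to its antipode when needed so that the azimuth of
    its XY projection lies in [0°, 180°).  Vectors parallel to z have no
    defined azimuth; ϕ = 0 is returned with ``phi_defined=False``.

    Raises
    ------
    ValueError
        If ``v`` is the zero vector.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not n > atol:
        raise ValueError("cannot orient a zero vector")
    v = v / n
    # snap vanishing components so boundary cases canonicalize consistently
    v = np.where(np.abs(v) <= atol, 0.0, v)
    xy = np.hypot(v[0], v[1])
    if xy == 0.0:
        # parallel to z: polar angle 0 by axis identification, azimuth undefined
        return OrientationAxis(theta=0.0, phi=0.0, phi_defined=False)
    # flip into the half sphere 0 <= phi < 180 (y > 0, or y == 0 and x > 0)
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    phi = float(np.degrees(np.arctan2(v[1], v[0]))) % 180.0
    theta = float(np.degrees(np.arccos(np.clip(v[2], -1.0, 1.0))))
    return OrientationAxis(theta=theta, phi=phi)


def axis_from_angles(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector for polar angle θ and azimuth ϕ (degrees)."""
    t = np.radians(theta_deg)
    p = np.radians(phi_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def orientation_heatmap(
    thetas,
    phis,
    bin_deg: float = 20.0,
    normalization: str = "counts",
    volume_mm3: float | None = None,
):
    """2D histogram of axis orientations over (θ, ϕ).

    Parameters
    ----------
    thetas, phis:
        Canonical angles in degrees (θ in [0, 180), ϕ in [0, 180)).
    bin_deg:
        Bin width in degrees (default 20°).
    normalization:
        ``"counts"`` (raw), ``"unit_area"`` (density integrating to 1 over the
        angle plane) or ``"unit_volume"`` (counts per mm³; requires
        ``volume_mm3``).

    Returns
    -------
    hist, theta_edges, phi_edges, peak:
        The binned map, the bin edges, and the (θ, ϕ) centre of the peak bin.
    """
    thetas = np.asarray(thetas, dtype=float)
    phis = np.asarray(phis, dtype=float)
    if thetas.size == 0:
        raise ValueError("need at least one orientation record")
    edges_t = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    edges_p = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    hist, _, _ = np.histogram2d(thetas, phis, bins=(edges_t, edges_p))
    if normalization == "unit_area":
        total = hist.sum() * bin_deg * bin_deg
        if total > 0:
            hist = hist / total
    elif normalization == "unit_volume":
        if volume_mm3 is None or volume_mm3 <= 0:
            raise ValueError("unit_volume normalization requires volume_mm3 > 0")
        hist = hist / volume_mm3
    elif normalization != "counts":
        raise ValueError(f"unknown normalization {normalization!r}")
    it, ip = np.unravel_index(np.argmax(hist), hist.shape)
    peak = (edges_t[it] + bin_deg / 2.0, edges_p[ip] + bin_deg / 2.0)
    return hist, edges_t, edges_p, peak


def phi_frequency(phis, bin_deg: float = 20.0):
    """Frequency distribution of ϕ normalized to unit area.

    Returns (density, bin_edges) with density integrating to 1 over [0°, 180°).
    """
    phis = np.asarray(phis, dtype=float)
    edges = np.arange(0.0, 180.0 + bin_deg, bin_deg)
    counts, _ = np.histogram(phis, bins=edges)
    total = counts.sum() * bin_deg
    density = counts / total if total > 0 else counts.astype(float)
    return density, edges
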