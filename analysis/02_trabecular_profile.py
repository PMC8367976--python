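"""Spatially resolved trabecular morphometry on lattice phantoms.

Builds (a) a homogeneous parallel-plate lattice (100 µm plates / 100 µm gaps,
the scale of rat calcaneal trabeculae) and (b) a lattice with linearly graded
spacing, then marches 0.75 mm cubic VOIs in steps of 0.375 mm along x and
reports BV/TV, Tb.Th, Tb.Sp, DA and the preferred orientation per VOI.
Writes results/trabecular_voi_homogeneous.csv and _graded.csv.
"""

from pathlib import Path

import numpy as np

from enthemorph.phantoms import make_trabecular_phantom
from enthemorph.preprocess import RegionSpec, marching_voi_grid
from enthemorph.trabecular import bone_volume_fraction, voi_metrics_table
from enthemorph.volume import BinaryVolume

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

# homogeneous lattice: full per-VOI morphometry
vol, truth = make_trabecular_phantom(
    (300, 160, 160), voxel_size=5.0, mode="plates", thickness_um=100.0,
    spacing_um=100.0, fabric_axis=(0, 0, 1), phase_offset_um=150.0, seed=0,
)
region = RegionSpec("trabecular", np.ones(vol.shape, bool), 5.0)
vois = marching_voi_grid(region, 0.75, 0.375, direction=0)
table = voi_metrics_table(vol, vois, n_directions=64, seed=0)
table.to_csv(OUT / "trabecular_voi_homogeneous.csv", index=False)
print(f"Homogeneous plate lattice ({len(vois)} VOIs, analytic BV/TV "
      f"{truth.meta['bvtv_analytic_pct']:.1f}%):")
print(table.round(2).to_string(index=False))

# graded lattice: BV/TV gradient recovery
graded, _ = make_trabecular_phantom(
    (450, 160, 160), voxel_size=5.0, mode="plates", thickness_um=100.0,
    spacing_um=60.0, spacing_end_um=150.0, fabric_axis=(1, 0, 0), seed=0,
)
region = RegionSpec("trabecular", np.ones(graded.shape, bool), 5.0)
rows = []
for box in marching_voi_grid(region, 0.75, 0.375, direction=0):
    pos = (box[0].start + box[0].stop) / 2 * 5.0 * 1e-3
    rows.append((pos, bone_volume_fraction(BinaryVolume(graded.grid[box], 5.0))))
pos, bv = np.array(rows).T
slope = np.polyfit(pos, bv, 1)[0]
expected = (100 / 250 - 100 / 160) * 100 / (450 * 5e-3)
import pandas as pd

pd.DataFrame({"position_mm": pos, "bvtv_pct": bv}).to_csv(
    OUT / "trabecular_voi_graded.csv", index=False
)
print(f"\nGraded lattice: fitted BV/TV slope {slope:.2f} %/mm "
      f"(constructed {expected:.2f} %/mm)")
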