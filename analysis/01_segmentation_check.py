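"""Segmentation robustness: Gaussian filtering + Otsu on degraded phantoms.

Degrades a channel-network phantom with blur and additive noise at several
noise levels, re-segments with the standard 3x3x3 Gaussian filter (sigma 0.65
voxels) and a global Otsu threshold, and measures voxel agreement with the
clean ground-truth mask.  Writes results/segmentation_agreement.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from enthemorph.phantoms import degrade, make_tube_phantom
from enthemorph.preprocess import binarize, gaussian_smooth, otsu_threshold

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

vol, _ = make_tube_phantom(
    (96, 72, 72), voxel_size=1.25, n_tubes=12, mean_axis=(1, 0.2, 0),
    axis_dispersion_deg=12.0, radius_um=(5.0, 12.0), length_um=(50.0, 100.0),
    seed=0,
)

rows = []
for noise_sd in (0.05, 0.10, 0.20, 0.30):
    for seed in range(5):
        noisy = degrade(vol, blur_sigma_um=1.25, noise_sd=noise_sd, seed=seed)
        smoothed = gaussian_smooth(noisy)
        thr = otsu_threshold(smoothed)
        seg = binarize(smoothed, thr)
        rows.append(
            {
                "noise_sd": noise_sd,
                "seed": seed,
                "otsu_threshold": thr,
                "agreement_pct": 100.0 * float((seg.grid == vol.grid).mean()),
            }
        )
table = pd.DataFrame(rows)
table.to_csv(OUT / "segmentation_agreement.csv", index=False)

summary = table.groupby("noise_sd")["agreement_pct"].agg(["mean", "min"])
print("Voxel agreement of Otsu segmentation with the clean mask:")
print(summary.round(3))
print(
    f"\nAt 10% noise the filtered+Otsu pipeline recovers the clean mask on "
    f"{summary.loc[0.10, 'min']:.2f}% of voxels (worst of 5 noise seeds)."
)
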