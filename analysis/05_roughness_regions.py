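"""Interface roughness across three region-like roughness levels.

Generates mineralization-front phantoms at three prescribed RMS levels
(rough tuberosity-like, intermediate periosteal-like, smooth cortical-like),
measures Pq on 10 sections per region with the 5th-order polynomial
reference, runs the group-comparison decision tree between regions, and
checks robustness of the regional ordering against segmentation-threshold
offsets.  Writes results/roughness_sections.csv and roughness_tests.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from enthemorph.phantoms import make_interface_phantom
from enthemorph.roughness import measure_roughness, threshold_sensitivity
from enthemorph.stats import compare_groups

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

LEVELS = {"tuberosity": 12.0, "periosteal": 7.0, "cortical": 4.5}
BASE = (0.0, 25.0, -8.0, 15.0, 0.0, 5.0)

rows = []
for region, rms in LEVELS.items():
    for section in range(10):
        img, _ = make_interface_phantom(
            baseline_coeffs=BASE, roughness_rms_um=rms,
            seed=hash((region, section)) % 2**31,
        )
        res = measure_roughness(img, voxel_size=1.25)
        rows.append({"region": region, "section": section,
                     "target_rms_um": rms, "pq_um": res.pq_um})
table = pd.DataFrame(rows)
table.to_csv(OUT / "roughness_sections.csv", index=False)
means = table.groupby("region")["pq_um"].mean()
print("Mean Pq per region (10 sections each):")
print(means.round(2))

tests = {}
for a, b in (("tuberosity", "periosteal"), ("periosteal", "cortical"),
             ("tuberosity", "cortical")):
    rep = compare_groups(table.query("region == @a")["pq_um"],
                         table.query("region == @b")["pq_um"])
    tests[f"{a}_vs_{b}"] = {"test": rep.test_name, "p": rep.p_value}
    print(f"  {a} vs {b}: {rep.test_name}, p = {rep.p_value:.2e}")

# threshold sensitivity of the regional ordering
offsets = [-0.1, -0.05, 0.0, 0.05, 0.1]
ordering_ok = True
sens = {}
for region, rms in LEVELS.items():
    img, _ = make_interface_phantom(baseline_coeffs=BASE, roughness_rms_um=rms,
                                    seed=99)
    gray = np.where(img, 200.0, 50.0)
    t = threshold_sensitivity(gray, 125.0, offsets)
    sens[region] = t["pq_um"].tolist()
for k in range(len(offsets)):
    if not (sens["tuberosity"][k] > sens["periosteal"][k] > sens["cortical"][k]):
        ordering_ok = False
tests["ordering_robust_to_threshold"] = ordering_ok
(OUT / "roughness_tests.json").write_text(json.dumps(tests, indent=2))
print(f"\nRegional Pq ordering preserved at every threshold offset: {ordering_ok}")
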