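"""End-to-end pipeline driver on phantom (or user-supplied) volumes.

Runs preprocess -> region definition -> {trabecular, channels, lacunae,
roughness} -> stats and writes one results directory with a subdirectory per
stage, all CSV/JSON outputs, the log and the exact configuration used.  All
randomness flows from the single root seed in the configuration, so a rerun
with the same config produces byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import channels as ch
from . import lacunae as lac
from . import phantoms, preprocess, roughness, stats, trabecular
from .config import PipelineConfig
from .io import write_table
from .volume import BinaryVolume

__all__ = ["run_pipeline"]


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    phantom_domain: tuple[int, int, int] = (128, 128, 96),
) -> dict:
    """Execute the full phantom analysis graph and write a results bundle.

    Returns a dict of the headline quantities of every stage.  Any stage
    failure aborts with the stage name in the raised error; partial outputs
    already written are preserved.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    results: dict = {}
    seed = config.seed
    stage = "setup"
    try:
        # ---------------- phantoms ----------------
        stage = "phantoms"
        d = out / "phantoms"
        d.mkdir(exist_ok=True)
        tube_vol, tube_truth = phantoms.make_tube_phantom(
            phantom_domain,
            voxel_size=config.voxel_size_um,
            n_tubes=10,
            mean_axis=(1.0, 0.3, 0.0),
            axis_dispersion_deg=8.0,
            radius_um=(5.0, 10.0),
            length_um=(80.0, 160.0),
            seed=seed,
        )
        write_table(tube_truth.objects, d / "tube_truth.csv")
        trab_vol, trab_truth = phantoms.make_trabecular_phantom(
            (240, 160, 160),
            voxel_size=5.0,
            mode="plates",
            thickness_um=100.0,
            spacing_um=100.0,
            phase_offset_um=150.0,
            seed=seed + 1,
        )
        write_table(trab_truth.objects, d / "trabecular_truth.csv")
        lacuna_kwargs = dict(
            n_lacunae=40,
            voxel_size=config.voxel_size_um,
            volume_range_um3=(4000.0, 12000.0),
            axis_ratio=3.5,
            aggregate_size=5,
        )
        lac_vol, lac_truth = phantoms.make_lacuna_phantom(
            (160, 160, 110),
            orientation_mode="aligned",
            mean_angles_deg=(80.0, 30.0),
            arrangement="columns",
            seed=seed + 2,
            **lacuna_kwargs,
        )
        write_table(lac_truth.objects, d / "lacuna_truth.csv")
        iso_vol, iso_truth = phantoms.make_lacuna_phantom(
            (160, 160, 110),
            orientation_mode="isotropic",
            arrangement="clusters",
            seed=seed + 3,
            **lacuna_kwargs,
        )
        interface_img, interface_truth = phantoms.make_interface_phantom(
            width_um=config.roughness.mask_width_um,
            height_um=config.roughness.mask_height_um,
            voxel_size=config.voxel_size_um,
            baseline_coeffs=(0.0, 20.0, 0.0, -15.0, 0.0, 5.0),
            roughness_rms_um=10.0,
            seed=seed + 4,
        )
        _log(log, f"phantoms: {len(tube_truth.objects)} tubes, "
                  f"{len(lac_truth.objects)} aligned + {len(iso_truth.objects)} isotropic lacunae")

        # ---------------- preprocess ----------------
        stage = "preprocess"
        d = out / "preprocess"
        d.mkdir(exist_ok=True)
        degraded = phantoms.degrade(tube_vol, blur_sigma_um=config.voxel_size_um,
                                    noise_sd=0.1, seed=seed + 5)
        smoothed = preprocess.gaussian_smooth(
            degraded, sigma=config.smoothing.sigma,
            support_radius=config.smoothing.support_radius,
        )
        thr = preprocess.otsu_threshold(smoothed)
        seg = preprocess.binarize(smoothed, thr)
        agreement = float((seg.grid == tube_vol.grid).mean())
        _log(log, f"preprocess: Otsu threshold {thr:.4f}, "
                  f"voxel agreement with clean mask {100 * agreement:.2f}%")
        results["otsu_threshold"] = thr
        results["segmentation_agreement_pct"] = 100 * agreement

        # ---------------- trabecular ----------------
        stage = "trabecular"
        d = out / "trabecular"
        d.mkdir(exist_ok=True)
        region = preprocess.RegionSpec("trabecular", np.ones(trab_vol.shape, bool), 5.0)
        vois = preprocess.marching_voi_grid(
            region, side_mm=config.voi.side_mm, step_mm=config.voi.step_mm,
            direction=config.voi.direction,
        )
        table = trabecular.voi_metrics_table(
            trab_vol, vois, direction=config.voi.direction,
            n_directions=64, seed=seed + 6,
        )
        write_table(table, d / "voi_metrics.csv")
        results["n_vois"] = len(vois)
        if len(table):
            results["bvtv_mean_pct"] = float(table["bvtv_pct"].mean())
            results["da_mean"] = float(table["da"].mean())
        _log(log, f"trabecular: {len(vois)} VOIs, "
                  f"mean BV/TV {results.get('bvtv_mean_pct', float('nan')):.2f}%")

        # ---------------- channels ----------------
        stage = "channels"
        d = out / "channels"
        d.mkdir(exist_ok=True)
        ch_mask, ch_flags = ch.extract_channels(
            seg, erosion_depth_um=0.0, min_area_px=config.channels.min_area_px,
        )
        skel = ch.skeletonize_channels(ch_mask)
        records = ch.channel_morphometry(skel)
        write_table(ch.channel_table(records), d / "channel_table.csv")
        gm = ch.global_channel_metrics(ch_mask, tissue=None, n_directions=128, seed=seed + 7)
        results["ch_v_tv_pct"] = gm.ch_v_tv_pct
        results["ch_da"] = gm.ch_da
        results["n_channels"] = len(records)
        _log(log, f"channels: {len(records)} channels, Ch.V/TV {gm.ch_v_tv_pct:.2f}%, "
                  f"Ch.DA {gm.ch_da:.3f}")

        # ---------------- lacunae ----------------
        stage = "lacunae"
        d = out / "lacunae"
        d.mkdir(exist_ok=True)
        lrec = lac.extract_lacunae(
            lac_vol,
            vol_window_um3=(config.lacunae.vol_min_um3, config.lacunae.vol_max_um3),
        )
        irec = lac.extract_lacunae(
            iso_vol,
            vol_window_um3=(config.lacunae.vol_min_um3, config.lacunae.vol_max_um3),
        )
        write_table(lac.lacuna_table(lrec), d / "lacuna_table_aligned.csv")
        write_table(lac.lacuna_table(irec), d / "lacuna_table_isotropic.csv")
        region_mm3 = np.prod(lac_vol.shape) * (config.voxel_size_um * 1e-3) ** 3
        gmet = lac.lacuna_global_metrics(lrec, region_mm3)
        results["l_n"] = gmet.l_n
        results["l_v_tv_pct"] = gmet.l_v_tv_pct
        _log(log, f"lacunae: {gmet.l_n} aligned lacunae, L.V/TV {gmet.l_v_tv_pct:.2f}%")

        # ---------------- roughness ----------------
        stage = "roughness"
        d = out / "roughness"
        d.mkdir(exist_ok=True)
        res = roughness.measure_roughness(interface_img, voxel_size=config.voxel_size_um,
                                          order=config.roughness.poly_order)
        write_table(
            pd.DataFrame([{"pq_um": res.pq_um, "n_points": res.n_points,
                           "excluded": res.excluded, "reason": res.reason}]),
            d / "roughness.csv",
        )
        results["pq_um"] = res.pq_um
        results["pq_target_um"] = float(interface_truth.objects["target_rms_um"][0])
        _log(log, f"roughness: Pq {res.pq_um:.2f} µm "
                  f"(target {results['pq_target_um']:.2f} µm)")

        # ---------------- stats ----------------
        stage = "stats"
        d = out / "stats"
        d.mkdir(exist_ok=True)
        ang_a = [(r.orientation.theta, r.orientation.phi)
                 for r in lac.orientation_subset(lrec, config.lacunae.orientation_max_sphericity)]
        ang_b = [(r.orientation.theta, r.orientation.phi)
                 for r in lac.orientation_subset(irec, config.lacunae.orientation_max_sphericity)]
        if len(ang_a) >= 5 and len(ang_b) >= 5:
            rep = stats.ks2d_peacock(ang_a, ang_b, n_perm=config.stats.n_perm,
                                     seed=seed + 8)
            report = {
                "test": rep.test_name, "D": rep.statistic, "p": rep.p_value,
                "n1": rep.n1, "n2": rep.n2, **rep.meta,
            }
            results["ks2d_p"] = rep.p_value
        else:
            report = {"skipped": "too few elongated lacunae"}
        (d / "orientation_test.json").write_text(json.dumps(report, indent=2))
        _log(log, f"stats: aligned-vs-isotropic orientation test {report}")
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        (out / "log.txt").write_text("\n".join(log) + f"\nFAILED at stage {stage}: {err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    config.to_yaml(out / "config.yaml")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    return results
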