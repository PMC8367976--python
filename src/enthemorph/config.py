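"""Pipeline configuration: every analysis parameter with its study default.

All defaults are the printed protocol values: 3x3x3 Gaussian kernel with
sigma 0.65 voxels, Otsu global threshold, 0.75 mm VOI side stepped by half a
side, 125 µm surface-layer erosion, 20 px (2D) despeckle area, channel
aspect-ratio class bounds 0.1 and 1, lacuna volume window 1000-30000 µm³,
sphericity cutoff 0.6 for orientation statistics, 437.5 x 625 µm roughness
mask with a degree-5 reference and 10 sections about 30 µm apart, and
alpha = 0.05 for all tests.  The configuration round-trips losslessly
through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class SmoothingConfig:
    sigma: float = 0.65
    support_radius: int = 1


@dataclass
class VoiConfig:
    side_mm: float = 0.75
    step_mm: float = 0.375
    direction: int = 0


@dataclass
class ChannelConfig:
    erosion_depth_um: float = 125.0
    min_area_px: int = 20
    rho_thick: float = 1.0
    rho_extremely_slender: float = 0.1


@dataclass
class LacunaConfig:
    vol_min_um3: float = 1000.0
    vol_max_um3: float = 30000.0
    orientation_max_sphericity: float = 0.6


@dataclass
class RoughnessConfig:
    mask_width_um: float = 625.0
    mask_height_um: float = 437.5
    poly_order: int = 5
    n_sections: int = 10
    section_spacing_um: float = 30.0


@dataclass
class StatsConfig:
    alpha: float = 0.05
    n_perm: int = 2000


@dataclass
class PipelineConfig:
    voxel_size_um: float = 1.25
    seed: int = 0
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    voi: VoiConfig = field(default_factory=VoiConfig)
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    lacunae: LacunaConfig = field(default_factory=LacunaConfig)
    roughness: RoughnessConfig = field(default_factory=RoughnessConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def validate(self) -> None:
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not self.lacunae.vol_min_um3 < self.lacunae.vol_max_um3:
            raise ValueError("lacuna volume window is empty")
        if not 0 < self.stats.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "voxel_size_um" not in raw or raw["voxel_size_um"] is None:
            raise ValueError("config must supply voxel_size_um")
        cfg = cls(
            voxel_size_um=raw["voxel_size_um"],
            seed=raw.get("seed", 0),
            smoothing=SmoothingConfig(**raw.get("smoothing", {})),
            voi=VoiConfig(**raw.get("voi", {})),
            channels=ChannelConfig(**raw.get("channels", {})),
            lacunae=LacunaConfig(**raw.get("lacunae", {})),
            roughness=RoughnessConfig(**raw.get("roughness", {})),
            stats=StatsConfig(**raw.get("stats", {})),
        )
        cfg.validate()
        return cfg
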