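"""Layered pipeline configuration.

Every threshold and coefficient of the segmentation chain lives here with
its published default, so a run can be reproduced from the echoed config
alone. Values can be overridden from a YAML file whose top-level keys match
the section names (``air``, ``brain``, ``csf`` ...).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class AirConfig:
    #: soft-tissue subtraction threshold is mean + subtract_sigma * sd
    subtract_sigma: float = 3.0
    #: darkest fraction of the contoured ROI used to initialise air stats
    stats_fraction: float = 0.5
    #: refit cutoff multiplier for the iterative air-stats estimator
    refit_sigma: float = 4.0


@dataclass
class BrainConfig:
    stat_lo: float = 0.53
    stat_hi: float = 1.35
    grow_lo: float = 0.7
    grow_hi: float = 1.2
    #: in-plane white-matter uniformity window (mm)
    uniformity_window_mm: float = 10.0


@dataclass
class CsfConfig:
    #: CSF reference search window edge (mm, isotropic 3D)
    window_mm: float = 5.0
    #: CSF growing window is mean ± sigma * sd
    sigma: float = 2.0
    #: closing radius (mm) applied to the initial brain mask before the
    #: reference search, so near-enclosed CSF spaces are searchable
    closing_mm: float = 4.0


@dataclass
class SkullConfig:
    #: skull seed rim depth from the external body contour (cm)
    rim_cm: float = 1.0
    #: skull seed upper bound is mu_air + air_sigma * sigma_air
    air_sigma: float = 3.0
    #: skull growing upper bound is mu_CSF + csf_sigma * sigma_CSF
    csf_sigma: float = 2.0
    #: ray-sampling step (voxels) for the external-to-skull rule
    ray_step_vox: float = 1.0


@dataclass
class CannyConfig:
    sigma: float = 1.0
    #: hysteresis thresholds as fractions of the slice's max gradient
    low: float = 0.4
    high: float = 0.8
    #: largest edge gap bridged by the gap-closing step (mm)
    max_gap_mm: float = 10.0


@dataclass
class EyeConfig:
    threshold_coeff: float = 0.7
    diameter_cm: float = 4.0
    box_sup_cm: float = 5.0
    box_inf_cm: float = 7.0
    sphericity_cm: float = 1.0
    #: "half a typical eye size": "volume" (default) or "diameter" reading
    size_rule: str = "volume"


@dataclass
class BoneConfig:
    air_sigma: float = 3.0
    trab_window_mm: float = 5.0
    trab_sigma: float = 2.0


@dataclass
class SoftConfig:
    #: adjacent-slice context on each side for per-slice soft stats
    context_slices: int = 1
    fat_sigma: float = 2.0
    #: closing radius for the MR body mask (mm)
    body_closing_mm: float = 3.0


@dataclass
class MappingConfig:
    #: HU assigned to eyes (no published row; water-like soft tissue)
    eye_hu: float = 45.0


@dataclass
class PipelineConfig:
    air: AirConfig = field(default_factory=AirConfig)
    brain: BrainConfig = field(default_factory=BrainConfig)
    csf: CsfConfig = field(default_factory=CsfConfig)
    skull: SkullConfig = field(default_factory=SkullConfig)
    canny: CannyConfig = field(default_factory=CannyConfig)
    eye: EyeConfig = field(default_factory=EyeConfig)
    bone: BoneConfig = field(default_factory=BoneConfig)
    soft: SoftConfig = field(default_factory=SoftConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section, values in (d or {}).items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            for key, value in (values or {}).items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(sub, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
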