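"""Run configuration: every tunable of the pipeline with its default.

The configuration is a tree of small dataclasses mirroring the pipeline
stages.  It can be loaded from a YAML mapping whose keys follow the
``section.key`` layout (``roi.bg_sat_max``, ``stain.hue_low_deg``, ...) and
serialises back to a plain dict, from which a stable hash is derived for
output provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml


@dataclass
class RoiConfig:
    """Tissue-versus-background pixel classification.

    A pixel is background iff it is both nearly achromatic and bright
    (slide glass shows as near-white); the region of interest (ROI) is the
    complement.
    """

    bg_sat_max: float = 0.08
    bg_val_min: float = 0.90


@dataclass
class StainConfig:
    """DAB (brown chromogen) pixel classification within the ROI."""

    hue_low_deg: float = 10.0
    hue_high_deg: float = 50.0
    val_max: float = 0.98  # excludes glare


@dataclass
class TilesConfig:
    min_roi_frac: float = 0.40


@dataclass
class GridConfig:
    """Saturation-threshold grid shared by curve features: 0.10..0.50 step 0.02."""

    t_min: float = 0.10
    t_max: float = 0.50
    t_step: float = 0.02

    def values(self) -> np.ndarray:
        n = int(round((self.t_max - self.t_min) / self.t_step)) + 1
        return np.round(np.linspace(self.t_min, self.t_max, n), 10)


@dataclass
class UlbpConfig:
    substrate: str = "mask"  # "mask" | "saturation"
    similarity_threshold: float = 0.95


@dataclass
class CurveConfig:
    n_points: int = 10  # characteristic-curve downsampling target


@dataclass
class MorphologyConfig:
    t0: float = 0.10  # saturation threshold for the connectedness mask
    connectivity: int = 8


@dataclass
class LearnerConfig:
    kind: str = "logreg"  # "logreg" | "svm"
    C: float = 1.0
    svm_kernel: str = "rbf"
    max_iter: int = 2000


@dataclass
class PipelineConfig:
    roi: RoiConfig = field(default_factory=RoiConfig)
    stain: StainConfig = field(default_factory=StainConfig)
    tiles: TilesConfig = field(default_factory=TilesConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    ulbp: UlbpConfig = field(default_factory=UlbpConfig)
    curve: CurveConfig = field(default_factory=CurveConfig)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section, values in d.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section!r}")
            sub = getattr(cfg, section)
            if not isinstance(values, dict):
                raise TypeError(f"config section {section!r} must be a mapping")
            for key, val in values.items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key: {section}.{key}")
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def hash(self) -> str:
        """Stable short hash of the effective configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


DEFAULT_CONFIG = PipelineConfig()
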