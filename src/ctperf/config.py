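"""Pipeline configuration: a strict, nested key-value schema.

Defaults trace to the pipeline's clinical conventions (8-voxel ROI search
radius, bcSVD with 10% singular-value truncation, rCBF < 0.30 and
Tmax > 6 s thresholds).  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessingConfig:
    motion_correct: bool = True
    mask_threshold_hu: float = 2.0
    baseline_frames: int = 4


@dataclass
class RoiConfig:
    radius: float = 8.0
    metric: str = "euclidean"


@dataclass
class ValidityConfig:
    min_peak_enhancement: float = 80.0
    fwhm_max_aif: float = 12.0
    fwhm_max_vof: float = 20.0
    decay_min: float = 0.4
    decay_window_s: float = 15.0
    early_fraction: float = 2.0 / 3.0
    delay_min_s: float = 3.0
    delay_max_s: float = 12.0


@dataclass
class DeconvConfig:
    mode: str = "bcSVD"
    truncation_fraction: float = 0.10


@dataclass
class QuantConfig:
    rcbf_threshold: float = 0.30
    tmax_threshold_s: float = 6.0
    reference: str = "global_median"


@dataclass
class PipelineConfig:
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    roi: RoiConfig = field(default_factory=RoiConfig)
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    seed: int = 0

    def __post_init__(self):
        v, d, q = self.validity, self.deconv, self.quant
        if not 0 < q.rcbf_threshold < 1:
            raise ConfigError("quant.rcbf_threshold must be in (0, 1)")
        if q.tmax_threshold_s <= 0:
            raise ConfigError("quant.tmax_threshold_s must be positive")
        if not 0 <= d.truncation_fraction < 1:
            raise ConfigError("deconv.truncation_fraction must be in [0, 1)")
        if d.mode not in ("sSVD", "bcSVD"):
            raise ConfigError("deconv.mode must be sSVD or bcSVD")
        if not 0 <= v.delay_min_s < v.delay_max_s:
            raise ConfigError("validity delay window invalid")
        if self.roi.radius < 0:
            raise ConfigError("roi.radius must be >= 0")

    def rule_config(self):
        from .validity import RuleConfig

        v = self.validity
        return RuleConfig(
            min_peak_enhancement=v.min_peak_enhancement,
            fwhm_max={"AIF": v.fwhm_max_aif, "VOF": v.fwhm_max_vof},
            decay_min=v.decay_min,
            decay_window=v.decay_window_s,
            early_fraction=v.early_fraction,
            delay_window=(v.delay_min_s, v.delay_max_s),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {f.name: f for f in fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in sections:
                raise ConfigError(f"unknown config section {key!r}")
            f = sections[key]
            if f.name == "seed":
                kwargs[key] = int(value)
                continue
            sub_cls = f.default_factory().__class__
            valid = {sf.name for sf in fields(sub_cls)}
            unknown = set(value) - valid
            if unknown:
                raise ConfigError(f"unknown keys in {key}: {sorted(unknown)}")
            kwargs[key] = sub_cls(**value)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"malformed config: {e}") from e
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        return cls.from_dict(data)
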