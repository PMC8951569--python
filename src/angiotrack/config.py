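"""Run configuration: YAML file merged with CLI overrides.

Unknown keys are rejected so typos in a config file fail loudly instead of
silently falling back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .matching import REGION_BACKGROUND, REGION_FULL
from .segmentation import BRIGHT_ON_DARK, DARK_ON_BRIGHT, FrangiParams
from .templates import DEFAULT_DILATION_RADIUS


@dataclass
class SegmentationConfig:
    sigmas: list[float] = field(default_factory=lambda: [1.0, 2.0, 3.0, 4.0, 5.0])
    beta: float = 0.5
    c: float = 0.08
    polarity: str = DARK_ON_BRIGHT
    threshold: str | float = "otsu"
    min_component_px: int = 50
    closing_radius_px: int = 1

    def frangi_params(self) -> FrangiParams:
        if self.polarity not in (DARK_ON_BRIGHT, BRIGHT_ON_DARK):
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        return FrangiParams(
            sigmas=tuple(self.sigmas), beta=self.beta, c=self.c, polarity=self.polarity
        )


@dataclass
class DetectionConfig:
    fraction: float = 0.3
    include_postbolus: bool = False


@dataclass
class MatchingConfig:
    region: str = REGION_BACKGROUND
    dilation_radius_px: int = DEFAULT_DILATION_RADIUS

    def validate(self) -> None:
        if self.region not in (REGION_FULL, REGION_BACKGROUND):
            raise ValidationError(f"matching.region must be 'full' or 'background'")
        if self.dilation_radius_px < 0:
            raise ValidationError("matching.dilation_radius_px must be >= 0")


@dataclass
class OverlayConfig:
    predicted_color: list[int] = field(default_factory=lambda: [255, 255, 0])
    reference_color: list[int] = field(default_factory=lambda: [0, 255, 0])
    line_thickness: int = 1


@dataclass
class RunConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    overlay: OverlayConfig = field(default_factory=OverlayConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "detection": DetectionConfig,
    "matching": MatchingConfig,
    "overlay": OverlayConfig,
}


def _build_section(cls, data: dict, section: str):
    allowed = set(cls.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'"
        )
    return cls(**data)


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; None or a missing-section file yields defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level of config must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValidationError(f"{path}: unknown config section(s) {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    cfg = RunConfig(**kwargs)
    cfg.matching.validate()
    cfg.segmentation.frangi_params()  # validates ranges
    return cfg
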