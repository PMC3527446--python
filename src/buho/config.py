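"""Pipeline configuration: defaults, validation, round-trip serialisation.

Every tunable of the pipeline lives here with its calibrated default:
intensity cap 255, nuclear threshold at 60% of maximum, watershed gain 2,
minimum cell area 30 um^2, the eight-prototype similarity thresholds
(0.89, 0.88, 0.80, 0.88, 0.86, 0.86, 0.92, 0.85), positivity at >= 2 foci
per cell, proximity radius 0.5 um, and the 6-px size-reliability width.
Configs are loaded from YAML (JSON is a YAML subset), unknown keys are
rejected, and every numeric field is range-checked.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

DEFAULT_STS: tuple[float, ...] = (0.89, 0.88, 0.80, 0.88, 0.86, 0.86, 0.92, 0.85)


class ConfigError(ValueError):
    """Raised for unparseable, unknown-key or out-of-range configuration."""


@dataclass
class PreprocessingConfig:
    cap: float = 255.0
    stretch_low: float = 0.01
    stretch_high: float = 0.99
    wiener_window: int = 3
    unsharp_alpha: float = 0.2
    gain: float = 2.0


@dataclass
class SegmentationConfig:
    threshold_frac: float = 0.6
    min_cell_area_um2: float = 30.0
    foreground_frac: float = 0.2  # of the denoised+stretched foci-channel max


@dataclass
class DetectionConfig:
    bank_path: Optional[str] = None
    similarity_thresholds: Optional[list[float]] = None  # None = bank defaults
    use_sharpened_pass: bool = True
    min_focus_area_um2: float = 0.0  # 0 disables the floor (0.2 for S-foci)
    use_rotations: bool = False
    detect_on_denoised: bool = False  # detection runs on the clipped, unscaled channel


@dataclass
class QuantificationConfig:
    min_foci_for_positive: int = 2
    proximity_radius_um: float = 0.5
    size_reliability_width_px: int = 6
    size_mode: str = "merged"  # "halfmax" re-segments footprints for size studies


@dataclass
class ScreeningConfig:
    control_treatment: str = "none"


@dataclass
class ChannelConfig:
    nuclear_page: int = 0
    foci_page: int = 1
    object_page: Optional[int] = None


@dataclass
class PipelineConfig:
    """Fully-defaulted, validated pipeline configuration."""

    pixel_size_um: float = 0.2
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    quantification: QuantificationConfig = field(default_factory=QuantificationConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    # (section, key) -> inclusive numeric bounds
    ("", "pixel_size_um"): (1e-6, 100.0),
    ("preprocessing", "cap"): (1e-9, 65535.0),
    ("preprocessing", "stretch_low"): (0.0, 1.0),
    ("preprocessing", "stretch_high"): (0.0, 1.0),
    ("preprocessing", "wiener_window"): (3, 99),
    ("preprocessing", "unsharp_alpha"): (0.0, 1.0),
    ("preprocessing", "gain"): (1.0, 100.0),
    ("segmentation", "threshold_frac"): (1e-9, 1.0 - 1e-9),
    ("segmentation", "min_cell_area_um2"): (0.0, 1e6),
    ("segmentation", "foreground_frac"): (0.0, 1.0 - 1e-9),
    ("detection", "min_focus_area_um2"): (0.0, 1e6),
    ("quantification", "min_foci_for_positive"): (1, 1000),
    ("quantification", "proximity_radius_um"): (1e-9, 1e3),
    ("quantification", "size_reliability_width_px"): (1, 1000),
}


def _check_range(section: str, key: str, value: Any) -> None:
    bounds = _RANGES.get((section, key))
    if bounds is None or value is None:
        return
    lo, hi = bounds
    if not (lo <= value <= hi):
        name = f"{section}.{key}" if section else key
        raise ConfigError(f"{name} = {value!r} outside valid range [{lo}, {hi}]")


def _apply_section(obj: Any, data: dict[str, Any], section: str) -> None:
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in valid:
            name = f"{section}.{key}" if section else key
            raise ConfigError(f"unknown configuration key: {name}")
        _check_range(section, key, value)
        setattr(obj, key, value)


def validate_config(source: str | Path | dict[str, Any] | None = None) -> PipelineConfig:
    """Build a fully-defaulted, range-checked config.

    ``source`` may be a YAML/JSON file path, an already-parsed mapping, or
    None/empty for all defaults.  Unknown keys and out-of-range values
    raise :class:`ConfigError` naming the offending key.
    """
    if source is None:
        data: dict[str, Any] = {}
    elif isinstance(source, dict):
        data = dict(source)
    else:
        path = Path(source)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config file {path}: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        data = loaded

    cfg = PipelineConfig()
    sections = {
        "channels": cfg.channels,
        "preprocessing": cfg.preprocessing,
        "segmentation": cfg.segmentation,
        "detection": cfg.detection,
        "quantification": cfg.quantification,
        "screening": cfg.screening,
    }
    top_scalars = {"pixel_size_um"}
    for key, value in data.items():
        if key in sections:
            if value is None:
                continue
            if not isinstance(value, dict):
                raise ConfigError(f"section {key} must be a mapping")
            _apply_section(sections[key], value, key)
        elif key in top_scalars:
            _check_range("", key, value)
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"unknown configuration key: {key}")

    pp = cfg.preprocessing
    if not pp.stretch_low < pp.stretch_high:
        raise ConfigError("preprocessing.stretch_low must be < preprocessing.stretch_high")
    if pp.wiener_window % 2 == 0:
        raise ConfigError("preprocessing.wiener_window must be odd")
    if cfg.quantification.size_mode not in ("merged", "halfmax"):
        raise ConfigError("quantification.size_mode must be 'merged' or 'halfmax'")
    if cfg.detection.similarity_thresholds is not None:
        for st in cfg.detection.similarity_thresholds:
            if not (0 < st < 1):
                raise ConfigError(
                    f"detection.similarity_thresholds entry {st!r} outside (0, 1)"
                )
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config as YAML; round-trips through :func:`validate_config`."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
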