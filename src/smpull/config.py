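"""Pipeline configuration: YAML loading with strict validation.

A configuration file mirrors the module parameter dataclasses section by
section; unknown keys are rejected so typos fail loudly at load time. Every
numeric value passes through the owning dataclass's own validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .dlim import SpotDetectionParams
from .errors import ConfigError
from .smlm.drift import DriftParams
from .smlm.morphology import SegmentParams
from .synth.cohort import CohortSpec, MorphologyParams, PAPER_COUNT_PARAMS, DEFAULT_MORPHOLOGY_PARAMS
from .synth.imaging import BlinkModel, OpticsModel, make_drift

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    level: str = "metrics"             # cohort fidelity: "metrics" or "images"
    log_level: str = "INFO"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    optics: OpticsModel = field(default_factory=OpticsModel)
    storm_optics: OpticsModel = field(default_factory=lambda: OpticsModel.dstorm())
    blink: BlinkModel = field(default_factory=BlinkModel)
    detection: SpotDetectionParams = field(default_factory=SpotDetectionParams)
    drift: DriftParams = field(default_factory=DriftParams)
    segment: SegmentParams = field(default_factory=SegmentParams)
    sr_pixel_nm: float = 20.0
    storm_frames: int = 7000
    counts_only: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("metrics", "images"):
            raise ConfigError("level must be 'metrics' or 'images'")
        if self.sr_pixel_nm <= 0:
            raise ConfigError("sr_pixel_nm must be positive")


_SECTION_TYPES = {
    "cohort": CohortSpec,
    "optics": OpticsModel,
    "storm_optics": OpticsModel,
    "blink": BlinkModel,
    "detection": SpotDetectionParams,
    "drift": DriftParams,
    "segment": SegmentParams,
}


def _build(cls, mapping: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {where!r}")
    try:
        return cls(**mapping)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {where!r}: {exc}") from exc


def _build_cohort(mapping: dict) -> CohortSpec:
    mapping = dict(mapping)
    if "count_params" in mapping:
        cp = {}
        for key, pair in mapping["count_params"].items():
            grp, ch = key.split("/")
            cp[(grp, ch)] = (float(pair[0]), float(pair[1]))
        mapping["count_params"] = cp
    if "morphology_params" in mapping:
        mp = {}
        for key, sub in mapping["morphology_params"].items():
            grp, ch = key.split("/")
            mp[(grp, ch)] = _build(MorphologyParams, sub, f"morphology_params[{key}]")
        mapping["morphology_params"] = mp
    return _build(CohortSpec, mapping, "cohort")


def load_config(path) -> PipelineConfig:
    """Load and validate a pipeline YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    allowed = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key == "cohort":
            kwargs[key] = _build_cohort(value or {})
        elif key == "blink":
            m = dict(value or {})
            if isinstance(m.get("drift"), dict):
                m["drift"] = make_drift(**m["drift"])
            kwargs[key] = _build(BlinkModel, m, "blink")
        elif key in _SECTION_TYPES:
            kwargs[key] = _build(_SECTION_TYPES[key], value or {}, key)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    return cfg
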