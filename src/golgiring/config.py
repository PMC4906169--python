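"""Run configuration: YAML round trip with strict key validation.

A run config names a stage and carries every tunable threshold of that
stage, grouped in sections mirroring the library dataclasses.  Unknown keys
are rejected by name so that typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .frap import FrapParams
from .profiles import AnalysisConfig
from .synth import FrapSpec, GolgiPopulationSpec, ImagingParams, TrackSpec

STAGES = ("simulate", "classify", "frap", "track", "coloc", "gold", "compare")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LinkingParams:
    d_max_nm: float = 400.0
    max_gap: int = 1
    min_track_len: int = 5
    speed_method: str = "slope"


@dataclass(frozen=True)
class RunConfig:
    stage: str = "simulate"
    seed: int = 0
    log_level: str = "INFO"
    preset: str | None = None
    input: str | None = None
    input_b: str | None = None  # second channel / second sample
    output: str | None = None
    frame_interval_s: float = 5.0
    imaging: ImagingParams = field(default_factory=ImagingParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    frap_params: FrapParams = field(default_factory=FrapParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    golgi: GolgiPopulationSpec | None = None
    frap_spec: FrapSpec | None = None
    tracks: TrackSpec | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ConfigError(
                f"unknown stage {self.stage!r}; valid stages: {', '.join(STAGES)}"
            )


_SECTION_TYPES = {
    "imaging": ImagingParams,
    "analysis": AnalysisConfig,
    "frap_params": FrapParams,
    "linking": LinkingParams,
    "golgi": GolgiPopulationSpec,
    "frap_spec": FrapSpec,
    "tracks": TrackSpec,
}

_SCALAR_KEYS = {"stage", "seed", "log_level", "preset", "input", "input_b",
                "output", "frame_interval_s"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key {sorted(unknown)[0]!r} in section {section!r}"
        )
    if cls is ImagingParams and "field_size" in data:
        data = {**data, "field_size": tuple(data["field_size"])}
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    unknown = set(raw) - _SCALAR_KEYS - set(_SECTION_TYPES)
    if unknown:
        raise ConfigError(f"unknown config key {sorted(unknown)[0]!r}")
    kwargs = {k: raw[k] for k in _SCALAR_KEYS if k in raw}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            sub = raw[section]
            if not isinstance(sub, dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, sub, section)
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) config; empty file = defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return config_from_dict(raw)


def config_to_dict(cfg: RunConfig) -> dict:
    """Normalized plain-dict form (sections expanded, None sections dropped)."""
    out: dict = {}
    for key in sorted(_SCALAR_KEYS):
        val = getattr(cfg, key)
        if val is not None:
            out[key] = val
    for section in _SECTION_TYPES:
        val = getattr(cfg, section)
        if val is not None:
            d = dataclasses.asdict(val)
            if "field_size" in d:
                d["field_size"] = list(d["field_size"])
            out[section] = d
    return out


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))
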