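"""Run configuration: a validated YAML key tree.

All physical quantities are SI.  Unknown keys are rejected with a
suggestion; unit-suspicious values (a cylinder wider than the tank) are
refused; every applied default is logged.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .geometry import NU_WATER_15C

log = logging.getLogger("wakekin.config")


class ConfigError(ValueError):
    """Raised for unknown keys or physically inconsistent values."""


@dataclass
class GeometryConfig:
    D: float = 0.019                  # cylinder diameter, m
    W: float = 0.25                   # tank width, m
    lx_over_d: float = 1.9
    ly_over_d: float = 3.0
    rows: int = 3                     # cross-stream
    columns: int = 5                  # streamwise


@dataclass
class FlowConfig:
    speeds_Uf: list = field(default_factory=lambda: [0.22, 0.48, 0.74])  # m/s
    nu: float = NU_WATER_15C          # m^2/s
    strouhal: float = 0.21


@dataclass
class VideoConfig:
    frame_rate: float = 100.0         # Hz
    scale: float = 1.0                # m per coordinate unit


@dataclass
class FishConfig:
    body_length: float = 0.074        # m
    com_fraction: float = 0.35        # assumed when not measured


@dataclass
class AnalysisConfig:
    probe_x: float | None = None      # default: 2 pitches downstream
    probe_y: float = 0.0
    min_likelihood: float = 0.9
    max_gap: int = 5
    inaccurate_threshold: float = 0.10
    beats_per_sequence: int = 4
    n_design_samples: int = 24
    design_bounds: list = field(default_factory=lambda: [[1.9, 3.5], [1.9, 3.5]])
    seed: int = 0


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)
    video: VideoConfig = field(default_factory=VideoConfig)
    fish: FishConfig = field(default_factory=FishConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> "RunConfig":
        g = self.geometry
        if g.D <= 0 or g.W <= 0:
            raise ConfigError("geometry.D and geometry.W must be positive")
        if g.D >= g.W:
            raise ConfigError(
                f"geometry.D={g.D} is not smaller than tank width geometry.W={g.W}; "
                "check units (meters expected)"
            )
        if any(u <= 0 for u in self.flow.speeds_Uf):
            raise ConfigError("flow.speeds_Uf must be positive")
        if self.video.frame_rate <= 0 or self.video.scale <= 0:
            raise ConfigError("video.frame_rate and video.scale must be positive")
        if not 0 < self.fish.com_fraction < 1:
            raise ConfigError("fish.com_fraction must be in (0, 1)")
        if self.fish.body_length <= 0:
            raise ConfigError("fish.body_length must be positive")
        return self


_SECTIONS = {
    "geometry": GeometryConfig,
    "flow": FlowConfig,
    "video": VideoConfig,
    "fish": FishConfig,
    "analysis": AnalysisConfig,
}


def _suggest(key: str, valid) -> str:
    """Best-guess hint for a mistyped key (prefix match, then fuzzy)."""
    lower = key.lower()
    prefixes = [
        v for v in valid if lower.startswith(v.lower()) or v.lower().startswith(lower)
    ]
    if prefixes:
        return f"; did you mean {min(prefixes, key=len)!r}?"
    hint = difflib.get_close_matches(key, valid, n=1, cutoff=0.5)
    return f"; did you mean {hint[0]!r}?" if hint else ""


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    obj_kwargs = {}
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(
                f"unknown key {section}.{key!r}{_suggest(key, valid)} "
                f"(valid keys: {sorted(valid)})"
            )
        obj_kwargs[key] = value
    for name in valid - set(obj_kwargs):
        log.info("config: %s.%s not given, using default", section, name)
    return cls(**obj_kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; missing keys get logged defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping at top level")
    if overrides:
        for k, v in overrides.items():
            data.setdefault(k, {}).update(v)
    kwargs = {}
    for key, value in data.items():
        if key not in _SECTIONS:
            raise ConfigError(
                f"unknown section {key!r}{_suggest(key, _SECTIONS)} "
                f"(valid sections: {sorted(_SECTIONS)})"
            )
        if not isinstance(value, dict):
            raise ConfigError(f"section {key!r} must be a mapping")
        kwargs[key] = _build_section(_SECTIONS[key], value, key)
    for name in _SECTIONS.keys() - kwargs.keys():
        log.info("config: section %r not given, using defaults", name)
    return RunConfig(**kwargs).validate()
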