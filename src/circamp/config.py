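"""Run configuration: a single validated YAML/JSON document drives a full
analysis (models, pulse protocol, schedule preset, seeds, output paths),
so every figure-style output is regenerable from one command."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .oscillators import DEFAULT_DLMO_OFFSET, DEFAULT_DT, MODEL_NAMES

__all__ = ["RunConfig", "load_config", "dump_config"]

_PROTOCOL_DEFAULTS = {
    "duration": 1.0,
    "intensity": 8000.0,
    "background": 0.0,
    "reference": "pulse_center",
}
_SCHEDULE_DEFAULTS = {
    "preset": "regular",  # regular | jittered | calibrated
    "file": None,
    "n_days": 14,
    "onset_clock": 23.0,
    "duration": 8.0,
    "onset_jitter": 0.0,
    "duration_jitter": 0.0,
    "target_sri": None,
    "epoch_minutes": 1,
}
_DRIFT_DEFAULTS = {"value": None, "interval": None}


@dataclass
class RunConfig:
    models: list = field(default_factory=lambda: ["forger99"])
    dt: float = DEFAULT_DT
    dlmo_offset: float = DEFAULT_DLMO_OFFSET
    grid_spacing: float = 0.5
    wake_lux: float = 500.0
    seed: int = 0
    outdir: str = "out"
    protocol: dict = field(default_factory=lambda: dict(_PROTOCOL_DEFAULTS))
    schedule: dict = field(default_factory=lambda: dict(_SCHEDULE_DEFAULTS))
    drift: dict = field(default_factory=lambda: dict(_DRIFT_DEFAULTS))

    def __post_init__(self):
        if isinstance(self.models, str):
            self.models = [self.models]
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ValueError(
                f"unknown model name(s) {unknown}; registered models: {list(MODEL_NAMES)}"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.grid_spacing > 0:
            raise ValueError("grid_spacing must be positive")
        if self.wake_lux < 0:
            raise ValueError("wake_lux must be >= 0")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for name, defaults in (
            ("protocol", _PROTOCOL_DEFAULTS),
            ("schedule", _SCHEDULE_DEFAULTS),
            ("drift", _DRIFT_DEFAULTS),
        ):
            given = getattr(self, name) or {}
            bad = sorted(set(given) - set(defaults))
            if bad:
                raise ValueError(f"unknown {name} keys: {bad}")
            merged = dict(defaults)
            merged.update(given)
            setattr(self, name, merged)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config file, filling all defaults.

    Unknown top-level or nested keys are rejected; unknown model names
    raise an error listing the registered models.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = sorted(set(raw) - known)
    if bad:
        raise ValueError(f"unknown config keys: {bad}; known keys: {sorted(known)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.as_dict(), sort_keys=False))
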