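"""Configuration loading with validated defaults.

One YAML (or JSON) file drives the generator, the state spaces, the
learner and the pipeline.  Every default is the corresponding published
model parameter (tau 0.05/s, eta_r 0.5, gamma 0.95, eta_d 0.3, CV_d 0.05,
dwell floor 1e-4, 3 Hz baseline with gains 5 and 2, observation weights
0.95/0.05/1e-4, lesion parameters 0.55/0.45 and 0.15); an empty file
yields exactly that set.  Unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .generate import SessionConfig
from .learning import LearnerHyper
from .pipeline import ExperimentConfig

__all__ = ["AppConfig", "LesionParams", "load_config", "save_config",
           "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema; the message names the
    offending key and constraint."""


@dataclass
class LesionParams:
    cue_to_same_well: float = 0.55
    transition_floor: float = 0.15

    def __post_init__(self) -> None:
        if not 0.5 <= self.cue_to_same_well <= 1.0:
            raise ConfigError("lesion.cue_to_same_well must be in [0.5, 1]")
        if not 0.0 < self.transition_floor <= 0.25:
            raise ConfigError("lesion.transition_floor must be in (0, 0.25]")


@dataclass
class AppConfig:
    session: SessionConfig = field(default_factory=SessionConfig)
    hyper: LearnerHyper = field(default_factory=LearnerHyper)
    lesion: LesionParams = field(default_factory=LesionParams)
    n_sims: int = 20
    n_sessions: int = 30
    exclude_sessions: int = 10
    d_max: int = 150

    def experiment(self) -> ExperimentConfig:
        return ExperimentConfig(session=self.session, hyper=self.hyper,
                                n_sims=self.n_sims, n_sessions=self.n_sessions,
                                exclude_sessions=self.exclude_sessions,
                                d_max=self.d_max)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {"session": SessionConfig, "hyper": LearnerHyper,
                  "lesion": LesionParams}
_SCALAR_KEYS = {"n_sims", "n_sessions", "exclude_sessions", "d_max"}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section "
                          f"{section!r}; valid keys: {sorted(valid)}")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path: str | Path | None = None) -> AppConfig:
    """Load and validate a configuration file; ``None`` (or an empty file)
    yields the full default parameter set."""
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
    unknown = set(data) - set(_SECTION_TYPES) - _SCALAR_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; valid: "
                          f"{sorted(set(_SECTION_TYPES) | _SCALAR_KEYS)}")
    sections = {name: _build_section(cls, data.get(name, {}) or {}, name)
                for name, cls in _SECTION_TYPES.items()}
    scalars = {}
    for key in _SCALAR_KEYS:
        if key in data:
            v = data[key]
            if not isinstance(v, int) or v < 0:
                raise ConfigError(f"{key} must be a nonnegative integer")
            scalars[key] = v
    return AppConfig(**sections, **scalars)


def save_config(config: AppConfig, path: str | Path) -> None:
    path = Path(path)
    payload = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def config_hash(config: AppConfig) -> str:
    """Stable digest of the full configuration (reproducibility manifest)."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
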