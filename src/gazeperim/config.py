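"""Run configuration: a validated, serializable bundle of every knob.

A :class:`RunConfig` aggregates the screen model, viewer defaults, ZEST
parameters, classifier eccentricity model, session orchestration, the
hill-of-vision generator, and observer behaviour.  It round-trips
losslessly through YAML or JSON; every default is overridable and unknown
keys are rejected with the offending key named.

Units throughout: angles in degrees, times in seconds, luminance in
cd/m^2, trial indices 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .classifier import EccentricityModel
from .geometry import ScreenModel
from .observer import HillModel, ObserverBehavior
from .session import SessionConfig
from .zest import PriorSpec, ZestConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    eye: str = "right"
    seed: int = 0
    n_observers: int = 1
    screen: ScreenModel = ScreenModel()
    zest: ZestConfig = ZestConfig()
    classifier: EccentricityModel = EccentricityModel()
    session: SessionConfig = SessionConfig()
    hill: HillModel = HillModel()
    behavior: ObserverBehavior = ObserverBehavior()
    viewing_distance_cm: float = 60.0
    trackbox_deg: tuple[float, float] = (27.0, 15.0)
    #: rendered edge blur of the physical stimulus (recorded, not rendered)
    stimulus_blur_sigma_deg: float = 0.05

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise ConfigError(f"eye must be 'left' or 'right', got {self.eye!r}")
        if self.n_observers < 0:
            raise ConfigError("n_observers must be >= 0")


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def _from_plain(cls: type, data: Any, path: str) -> Any:
    if not (is_dataclass(cls) and isinstance(data, dict)):
        return data
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        target = f.type if isinstance(f.type, type) else None
        default = getattr(cls, name, None)
        nested = _nested_type(cls, name)
        if nested is not None and isinstance(value, dict):
            kwargs[name] = _from_plain(nested, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            kwargs[name] = _as_tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config under '{path or 'root'}': {exc}") from exc


def _as_tuple(value: list) -> tuple:
    return tuple(_as_tuple(v) if isinstance(v, list) else v for v in value)


_NESTED = {
    "screen": ScreenModel,
    "zest": ZestConfig,
    "classifier": EccentricityModel,
    "session": SessionConfig,
    "hill": HillModel,
    "behavior": ObserverBehavior,
    "prior": PriorSpec,
    "blind_spot_prior": PriorSpec,
}


def _nested_type(cls: type, name: str) -> type | None:
    return _NESTED.get(name)


def to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; an empty or missing-section file means defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else None
    else:
        data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _from_plain(RunConfig, data, "")


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    plain = _to_plain(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(plain, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(plain, sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of a config, for provenance blocks."""
    blob = json.dumps(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
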