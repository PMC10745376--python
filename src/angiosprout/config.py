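"""Analysis configuration: YAML round-trip and defaults.

One :class:`AnalysisConfig` carries everything a plate run needs: physical
calibration, channel-role mapping, and the parameter blocks of the three
detection stages.  Precedence is CLI flag > YAML file > built-in default,
and the effective config is dumped alongside results for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .chip_geometry import GuideDetectionParams
from .nuclei_quant import NucleiParams
from .sprout_quant import FiberParams


class ConfigError(ValueError):
    """Configuration schema violation; the message names the key path."""


@dataclass(frozen=True)
class AnalysisConfig:
    pixel_size_um: float = 2.0
    z_step_um: float = 5.0
    channels: dict = field(default_factory=lambda: {"nuclear": "nuclear", "actin": "actin"})
    flip_y: bool = False
    geometry: GuideDetectionParams = field(default_factory=GuideDetectionParams)
    sprouts: FiberParams = field(default_factory=FiberParams)
    nuclei: NucleiParams = field(default_factory=NucleiParams)

    def to_dict(self) -> dict[str, Any]:
        return {
            "pixel_size_um": self.pixel_size_um,
            "z_step_um": self.z_step_um,
            "channels": dict(self.channels),
            "flip_y": self.flip_y,
            "geometry": dataclasses.asdict(self.geometry),
            "sprouts": dataclasses.asdict(self.sprouts),
            "nuclei": dataclasses.asdict(self.nuclei),
        }

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from YAML plus flat overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = loaded
    if overrides:
        data = _deep_merge(data, overrides)
    return _from_dict(data)


def _from_dict(data: dict[str, Any]) -> AnalysisConfig:
    known = {"pixel_size_um", "z_step_um", "channels", "flip_y", "geometry", "sprouts", "nuclei"}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")
    kwargs: dict[str, Any] = {}
    for key in ("pixel_size_um", "z_step_um", "channels", "flip_y"):
        if key in data:
            kwargs[key] = data[key]
    for key, cls in (("geometry", GuideDetectionParams), ("sprouts", FiberParams), ("nuclei", NucleiParams)):
        if key in data:
            block = data[key]
            if not isinstance(block, dict):
                raise ConfigError(f"{key}: must be a mapping")
            valid = {f.name for f in dataclasses.fields(cls)}
            for sub in block:
                if sub not in valid:
                    raise ConfigError(f"{key}.{sub}: unknown parameter")
            try:
                kwargs[key] = cls(**block)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{key}: {exc}") from exc
    try:
        return AnalysisConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
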