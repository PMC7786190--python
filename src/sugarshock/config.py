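"""Run configuration: presets, overrides and YAML/JSON loading.

A :class:`RunConfig` resolves to a fully explicit, serializable description
of a pipeline run.  Defaults are the wild-type parameter table; a config
file may select the ``U224G`` preset and/or override individual parameters.
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .ensemble import DEFAULT_SCHEDULE_MIN
from .errors import ConfigurationError
from .network import Variant
from .parameters import KineticParameters, preset

__all__ = ["RunConfig", "load_config"]

_TOP_LEVEL_KEYS = {
    "preset",
    "params",
    "variant",
    "n_replicates",
    "schedule_min",
    "base_seed",
    "cells_per_timepoint",
    "grid_points",
    "bandwidth",
    "maxfev",
    "free_parameters",
    "bounds",
    "noise_background_mean",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for any pipeline stage."""

    params: KineticParameters = field(default_factory=KineticParameters)
    preset_name: str = "WT"
    variant: Variant = Variant.FULL
    n_replicates: int = 2000
    schedule_min: tuple[float, ...] = DEFAULT_SCHEDULE_MIN
    base_seed: int = 0
    cells_per_timepoint: int | None = None
    grid_points: int = 512
    bandwidth: float | None = None
    maxfev: int = 60
    free_parameters: tuple[str, ...] = ()
    bounds: dict = field(default_factory=dict)
    noise_background_mean: float = 0.0

    def to_dict(self) -> dict[str, Any]:
        return {
            "preset": self.preset_name,
            "params": self.params.to_dict(),
            "variant": self.variant.value,
            "n_replicates": self.n_replicates,
            "schedule_min": list(self.schedule_min),
            "base_seed": self.base_seed,
            "cells_per_timepoint": self.cells_per_timepoint,
            "grid_points": self.grid_points,
            "bandwidth": self.bandwidth,
            "maxfev": self.maxfev,
            "free_parameters": list(self.free_parameters),
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "noise_background_mean": self.noise_background_mean,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _from_mapping(raw: Mapping[str, Any]) -> RunConfig:
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    preset_name = str(raw.get("preset", "WT"))
    params = preset(preset_name)
    overrides = raw.get("params") or {}
    if not isinstance(overrides, Mapping):
        raise ConfigurationError("'params' must be a mapping of overrides")
    params = params.replace(**dict(overrides))
    defaults = RunConfig()
    return RunConfig(
        params=params,
        preset_name=preset_name,
        variant=Variant.coerce(raw.get("variant", defaults.variant)),
        n_replicates=int(raw.get("n_replicates", defaults.n_replicates)),
        schedule_min=tuple(
            float(t) for t in raw.get("schedule_min", defaults.schedule_min)
        ),
        base_seed=int(raw.get("base_seed", defaults.base_seed)),
        cells_per_timepoint=(
            None
            if raw.get("cells_per_timepoint") is None
            else int(raw["cells_per_timepoint"])
        ),
        grid_points=int(raw.get("grid_points", defaults.grid_points)),
        bandwidth=(
            None if raw.get("bandwidth") is None else float(raw["bandwidth"])
        ),
        maxfev=int(raw.get("maxfev", defaults.maxfev)),
        free_parameters=tuple(raw.get("free_parameters", ())),
        bounds={
            str(k): (float(v[0]), float(v[1]))
            for k, v in (raw.get("bounds") or {}).items()
        },
        noise_background_mean=float(
            raw.get("noise_background_mean", defaults.noise_background_mean)
        ),
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML or JSON config file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config file must contain a mapping")
    return _from_mapping(raw)
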