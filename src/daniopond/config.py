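"""Configuration schema and reproducibility shell.

A simulation is fully described by four blocks — ``deb`` (organism
parameters), ``food`` (pond food-web constants), ``ibm`` (population
constants) and ``run`` (scenario source, duration, replicates, seed,
output directory).  Defaults reproduce the calibrated zebrafish
configuration; a YAML file and/or keyword overrides are merged on top
(overrides win).  Unknown keys are rejected and every value is validated
by the corresponding dataclass, so a typo cannot silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deb import DEBParams
from .food import FoodParams
from .ibm import IBMParams

__all__ = ["RunSettings", "SimulationConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunSettings:
    """Scenario and execution settings."""

    scenario: str = "generate"      # "generate" or a path to a scenario TSV
    years: int = 4                  # generated-scenario length
    n_days: int = 1110              # simulation duration (d)
    replicates: int = 1
    seed: int = 0
    start_day_of_year: int = 121    # simulation day 1 = 1 May
    monsoon_start: int = 152        # day-of-year monsoon window
    monsoon_end: int = 273
    mean_temperature: float = 25.0  # generated-scenario climate shape
    amplitude: float = 6.0
    peak_day: int = 160
    output_dir: str = "daniopond_output"

    def __post_init__(self):
        if self.n_days < 1 or self.replicates < 1 or self.years < 1:
            raise ValueError("n_days, replicates and years must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    deb: DEBParams = field(default_factory=DEBParams)
    food: FoodParams = field(default_factory=FoodParams)
    ibm: IBMParams = field(default_factory=IBMParams)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        return {
            "deb": dataclasses.asdict(self.deb),
            "food": dataclasses.asdict(self.food),
            "ibm": dataclasses.asdict(self.ibm),
            "run": dataclasses.asdict(self.run),
        }

    def save_resolved(self, path) -> None:
        """Echo the fully resolved configuration (byte-stable key order)."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


_SECTIONS = {"deb": DEBParams, "food": FoodParams, "ibm": IBMParams, "run": RunSettings}


def load_config(path=None, overrides: dict | None = None) -> SimulationConfig:
    """Build a configuration from defaults → file → overrides.

    ``overrides`` is a mapping of section name → {key: value} (or flat
    ``"section.key"`` strings).  Unknown sections or keys raise with the
    offending name.
    """
    merged: dict = {k: {} for k in _SECTIONS}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping of sections")
        _merge(merged, raw, source=str(path))
    if overrides:
        flat: dict = {}
        for key, value in overrides.items():
            if isinstance(value, dict):
                flat.setdefault(key, {}).update(value)
            elif "." in key:
                section, name = key.split(".", 1)
                flat.setdefault(section, {})[name] = value
            else:
                raise ValueError(f"override {key!r} must be 'section.key' or a section mapping")
        _merge(merged, flat, source="overrides")
    built = {}
    for section, cls in _SECTIONS.items():
        try:
            built[section] = cls(**merged[section])
        except TypeError as exc:
            raise ValueError(f"config section [{section}]: {exc}") from None
    return SimulationConfig(**built)


def _merge(target: dict, raw: dict, source: str) -> None:
    for section, values in raw.items():
        if section not in _SECTIONS:
            raise ValueError(f"{source}: unknown config section {section!r}")
        if values is None:
            continue
        if not isinstance(values, dict):
            raise ValueError(f"{source}: section {section!r} must be a mapping")
        valid = {f.name for f in dataclasses.fields(_SECTIONS[section])}
        for key in values:
            if key not in valid:
                raise ValueError(f"{source}: unknown key {key!r} in section [{section}]")
        target[section].update(values)


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the resolved configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
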