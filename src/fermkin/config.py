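"""Simulation configuration: defaults, validation, file round-trip.

Config files are flat YAML mappings with dotted keys, e.g.::

    x0: 0.1
    t_total: 60
    schedule.kind: exponential
    schedule.T0: 40
    schedule.Tf: 20

Missing keys are filled from the documented defaults; unknown keys are
rejected.  Thermodynamic constants can be overridden per-run with the
``thermo.A1`` ... ``thermo.E4`` keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .kinetics import DEFAULT_THERMO, ThermoConstants
from .schedule import TemperatureSchedule

__all__ = ["ConfigError", "SimulationConfig", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """Raised for unknown keys or invariant violations in a config."""


_SCALAR_KEYS = {
    "x0": float,
    "p0": float,
    "alpha": float,
    "n": float,
    "dt": float,
    "t_total": float,
    "seed": int,
    "inhibition": str,
}
_SCHEDULE_KEYS = {"schedule.kind": str, "schedule.T0": float,
                  "schedule.Tf": float, "schedule.c": float}
_THERMO_KEYS = {f"thermo.{k}": float
                for k in ("A1", "A2", "A3", "A4", "E1", "E2", "E3", "E4")}
_ALL_KEYS = {**_SCALAR_KEYS, **_SCHEDULE_KEYS, **_THERMO_KEYS}


@dataclass(frozen=True)
class SimulationConfig:
    """Complete, validated description of one simulation run."""

    x0: float = 0.1
    p0: float = 0.0
    alpha: float = 2.2
    n: float = 1.0
    dt: float = 0.01
    t_total: float = 60.0
    seed: int = 0
    inhibition: str = "current"
    schedule: TemperatureSchedule = field(
        default_factory=lambda: TemperatureSchedule.constant(30.0)
    )
    thermo: ThermoConstants = field(default_factory=lambda: DEFAULT_THERMO)

    def __post_init__(self) -> None:
        checks = {
            "x0": self.x0 > 0,
            "p0": self.p0 >= 0,
            "alpha": self.alpha >= 0,
            "n": self.n > 0,
            "dt": self.dt > 0,
            "t_total": self.t_total >= 0,
            "inhibition": self.inhibition in ("current", "historical"),
        }
        for key, ok in checks.items():
            if not ok:
                raise ConfigError(
                    f"invalid value for {key!r}: {getattr(self, key)!r}"
                )

    def to_flat_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _SCALAR_KEYS}
        d["schedule.kind"] = self.schedule.kind
        d["schedule.T0"] = self.schedule.T0
        if self.schedule.kind == "exponential":
            d["schedule.Tf"] = self.schedule.Tf
            d["schedule.c"] = self.schedule.c
        for key in _THERMO_KEYS:
            d[key] = getattr(self.thermo, key.split(".", 1)[1])
        return d

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "SimulationConfig":
        unknown = sorted(set(flat) - set(_ALL_KEYS))
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
        kwargs = {}
        for key, cast in _SCALAR_KEYS.items():
            if key in flat:
                try:
                    kwargs[key] = cast(flat[key])
                except (TypeError, ValueError) as exc:
                    raise ConfigError(f"invalid value for {key!r}") from exc
        sched = {k.split(".", 1)[1]: v for k, v in flat.items()
                 if k in _SCHEDULE_KEYS}
        if sched:
            kind = sched.pop("kind", "constant")
            t_total = kwargs.get("t_total", cls.t_total)
            try:
                if kind == "constant":
                    kwargs["schedule"] = TemperatureSchedule.constant(
                        float(sched.get("T0", 30.0))
                    )
                else:
                    kwargs["schedule"] = TemperatureSchedule(
                        kind=kind,
                        T0=float(sched.get("T0", 40.0)),
                        Tf=(None if sched.get("Tf") is None
                            else float(sched["Tf"])),
                        c=(None if sched.get("c") is None
                           else float(sched["c"])),
                        t_total=t_total,
                    )
            except ValueError as exc:
                raise ConfigError(f"invalid schedule: {exc}") from exc
        thermo = {k.split(".", 1)[1]: float(v) for k, v in flat.items()
                  if k in _THERMO_KEYS}
        if thermo:
            try:
                kwargs["thermo"] = replace(DEFAULT_THERMO, **thermo)
            except ValueError as exc:
                raise ConfigError(f"invalid thermo constants: {exc}") from exc
        return cls(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a config file; an empty file yields the defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must be a flat key-value mapping")
    return SimulationConfig.from_flat_dict(raw)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_flat_dict(), sort_keys=True)
    )


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of a config snapshot, for run logging."""
    blob = json.dumps(config.to_flat_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
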