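"""Temperature schedules for batch fermentation.

Two laws are supported: a constant hold ``T(t) = T0`` and an exponential
decay ``T(t) = T0 * exp(-c * t)`` used to start a batch hot (fast initial
growth) and finish it cool (less ethanol stress).  Schedules operate on
the numeric Celsius value; conversion to Kelvin happens only inside the
Arrhenius evaluation.  For the decay law, the decay constant that reaches
``Tf`` at the horizon ``t_total`` is ``c = -ln(Tf / T0) / t_total``; past
the horizon the temperature is clamped at ``Tf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TemperatureSchedule", "decay_constant", "temperature_at"]


def decay_constant(T0: float, Tf: float, t_total: float) -> float:
    """Decay constant ``c = -ln(Tf / T0) / t_total`` (1/h).

    For the reference cooling strategy (40 -> 20 degC) this gives
    0.0116 1/h over 60 h and 0.0289 1/h over 24 h.
    """
    if T0 <= 0 or Tf <= 0:
        raise ValueError("temperatures must be positive (degC)")
    if t_total <= 0:
        raise ValueError("t_total must be positive")
    if Tf > T0:
        raise ValueError("Tf must not exceed T0 (cooling-only schedule)")
    return -math.log(Tf / T0) / t_total


@dataclass(frozen=True)
class TemperatureSchedule:
    """Constant or exponential-decay temperature law in degC.

    Prefer the :meth:`constant` and :meth:`exponential` constructors over
    direct instantiation.  For the exponential kind, supply ``Tf`` with
    ``t_total`` (``c`` is derived) or ``c`` with ``t_total`` (``Tf`` is
    derived); if both are given they must be consistent.
    """

    kind: str
    T0: float
    Tf: float | None = None
    c: float | None = None
    t_total: float | None = None

    def __post_init__(self) -> None:
        if self.T0 <= 0:
            raise ValueError("T0 must be positive (degC)")
        if self.kind == "constant":
            return
        if self.kind != "exponential":
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.t_total is None or self.t_total <= 0:
            raise ValueError("exponential schedule requires t_total > 0")
        if self.c is None and self.Tf is None:
            raise ValueError("exponential schedule requires Tf or c")
        if self.c is None:
            object.__setattr__(
                self, "c", decay_constant(self.T0, self.Tf, self.t_total)
            )
        elif self.c < 0:
            raise ValueError("c must be non-negative")
        implied_Tf = self.T0 * math.exp(-self.c * self.t_total)
        if self.Tf is None:
            object.__setattr__(self, "Tf", implied_Tf)
        elif not math.isclose(self.Tf, implied_Tf, rel_tol=1e-6):
            raise ValueError(
                f"inconsistent schedule: T(t_total)={implied_Tf:g} but Tf={self.Tf:g}"
            )

    @classmethod
    def constant(cls, T0: float) -> "TemperatureSchedule":
        return cls(kind="constant", T0=T0)

    @classmethod
    def exponential(
        cls, T0: float, Tf: float, t_total: float
    ) -> "TemperatureSchedule":
        return cls(kind="exponential", T0=T0, Tf=Tf, t_total=t_total)

    def __call__(self, t: float) -> float:
        return temperature_at(self, t)


def temperature_at(schedule: TemperatureSchedule, t: float) -> float:
    """Temperature (degC) of ``schedule`` at elapsed time ``t`` (h).

    Exponential schedules are clamped at ``Tf`` past their anchor horizon.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if schedule.kind == "constant":
        return schedule.T0
    if t >= schedule.t_total:
        return schedule.Tf
    return schedule.T0 * math.exp(-schedule.c * t)
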