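"""Batch ethanol fermentation kinetics.

The model tracks two state variables, cell mass ``x`` (g/L) and ethanol
``p`` (g/L), for *Saccharomyces cerevisiae* fermenting a glucose-replete
corn mash:

    dx/dt = mu * x
    dp/dt = (alpha * mu + beta) * x

``mu`` is the specific growth rate (1/h) and ``beta`` the specific rate of
non-growth-associated ethanol production (maintenance and energy-uncoupling
terms); ``alpha`` is the growth-associated yield (g ethanol per g new cell
mass), so the model is of the classic Luedeking-Piret growth-associated /
non-growth-associated form.  Both specific rates decay with the cells'
accumulated exposure to their own ethanol:

    mu   = mu0   * exp(-k'  * S),      S = sum_i p_i**n * dt
    beta = beta0 * exp(-k'' * S)

where ``n`` is the ethanol-inhibition degree and ``k'``/``k''`` are
deactivation constants.  The four temperature-dependent constants
``mu0, k', beta0, k''`` each follow an Arrhenius law ``A*exp(-E/(R*T))``
with empirically fitted frequency factors and activation energies.

State is advanced with explicit forward Euler on the same uniform grid on
which the discrete inhibition sum is accumulated; convergence to the
equivalent ODE limit is a tested property, not an assumption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "GAS_CONSTANT",
    "CELSIUS_OFFSET",
    "ThermoConstants",
    "DEFAULT_THERMO",
    "KineticParameters",
    "FermentationState",
    "Trajectory",
    "arrhenius_rate",
    "kinetic_params_at",
    "current_rates",
    "step",
    "simulate",
]

#: Gas constant in cal / (K mol), matching the activation-energy units.
GAS_CONSTANT = 1.987

CELSIUS_OFFSET = 273.15

#: Guard range for physically plausible fermentation temperatures (deg C).
_T_GUARD = (-20.0, 80.0)


@dataclass(frozen=True)
class ThermoConstants:
    """Arrhenius constants for the four kinetic parameters.

    ``(A1, E1)`` give the initial specific growth rate ``mu0`` (1/h),
    ``(A2, E2)`` the growth-path deactivation constant ``k'`` (L/(g h)),
    ``(A3, E3)`` the initial specific production rate ``beta0`` (1/h) and
    ``(A4, E4)`` the production-path deactivation constant ``k''``
    (L/(g h)).  Activation energies are in cal/mol.
    """

    A1: float = 8.84e8
    E1: float = 1.30e4
    A2: float = 7.12e14
    E2: float = 2.34e4
    A3: float = 1.48e7
    E3: float = 9.76e3
    A4: float = 1.76e4
    E4: float = 1.00e4
    R: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        for name in ("A1", "A2", "A3", "A4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("E1", "E2", "E3", "E4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.R <= 0:
            raise ValueError("R must be positive")


#: Empirical constants for S. cerevisiae on corn mash.
DEFAULT_THERMO = ThermoConstants()


@dataclass(frozen=True)
class KineticParameters:
    """Temperature-resolved kinetic parameter set.

    Rates carry 1/h units, deactivation constants L/(g h) (exact for
    inhibition degree ``n = 1``; ``(L/g)**n / h`` in general).
    """

    mu0: float
    beta0: float
    k_prime: float
    k_dprime: float
    alpha: float
    n: float

    def __post_init__(self) -> None:
        for name in ("mu0", "beta0", "k_prime", "k_dprime", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n <= 0:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class FermentationState:
    """Instantaneous fermentation state.

    ``s_p`` is the raw accumulated ethanol exposure ``sum p_i**n * dt``
    (g**n h / L**n).  ``s_mu`` and ``s_beta`` are the dimensionless
    inhibition exponents actually applied to ``mu`` and ``beta``; under the
    default current-temperature convention they equal ``k'(T) * s_p`` and
    ``k''(T) * s_p``, under the historical convention they are the running
    sums ``sum k'(T_i) p_i**n dt``.
    """

    t: float = 0.0
    x: float = 0.1
    p: float = 0.0
    s_mu: float = 0.0
    s_beta: float = 0.0
    s_p: float = 0.0

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("cell mass x must be positive")
        if self.p < 0:
            raise ValueError("ethanol p must be non-negative")
        if min(self.s_mu, self.s_beta, self.s_p) < 0:
            raise ValueError("inhibition accumulators must be non-negative")


def arrhenius_rate(A: float, E: float, T: float, R: float = GAS_CONSTANT) -> float:
    """Arrhenius rate ``A * exp(-E / (R * T))`` at absolute temperature ``T`` (K).

    Strictly increasing in ``T`` whenever ``E > 0``.
    """
    if A <= 0:
        raise ValueError("frequency factor A must be positive")
    if E < 0:
        raise ValueError("activation energy E must be non-negative")
    if T <= 0:
        raise ValueError("absolute temperature T must be positive")
    return A * math.exp(-E / (R * T))


def kinetic_params_at(
    temp_C: float,
    thermo: ThermoConstants = DEFAULT_THERMO,
    alpha: float = 2.2,
    n: float = 1.0,
) -> KineticParameters:
    """Evaluate the four Arrhenius laws at ``temp_C`` (deg C).

    ``alpha`` and ``n`` are temperature-independent and carried through.
    """
    if not _T_GUARD[0] <= temp_C <= _T_GUARD[1]:
        raise ValueError(
            f"temperature {temp_C} degC outside plausible range {_T_GUARD}"
        )
    T_K = temp_C + CELSIUS_OFFSET
    return KineticParameters(
        mu0=arrhenius_rate(thermo.A1, thermo.E1, T_K, thermo.R),
        k_prime=arrhenius_rate(thermo.A2, thermo.E2, T_K, thermo.R),
        beta0=arrhenius_rate(thermo.A3, thermo.E3, T_K, thermo.R),
        k_dprime=arrhenius_rate(thermo.A4, thermo.E4, T_K, thermo.R),
        alpha=alpha,
        n=n,
    )


def current_rates(
    state: FermentationState, params: KineticParameters
) -> tuple[float, float, float]:
    """Specific rates ``(mu, beta, v)`` at the given state.

    ``mu = mu0 * exp(-s_mu)``, ``beta = beta0 * exp(-s_beta)`` and the
    specific ethanol production rate ``v = alpha * mu + beta``.
    """
    mu = params.mu0 * math.exp(-state.s_mu)
    beta = params.beta0 * math.exp(-state.s_beta)
    return mu, beta, params.alpha * mu + beta


def _effective_state(
    state: FermentationState, params: KineticParameters, inhibition: str
) -> FermentationState:
    """State with inhibition exponents resolved for the given convention."""
    if inhibition == "current":
        return replace(
            state,
            s_mu=params.k_prime * state.s_p,
            s_beta=params.k_dprime * state.s_p,
        )
    if inhibition == "historical":
        return state
    raise ValueError(f"unknown inhibition convention {inhibition!r}")


def step(
    state: FermentationState,
    params: KineticParameters,
    dt: float,
    inhibition: str = "current",
) -> FermentationState:
    """Advance the state by one forward-Euler step of width ``dt`` (h).

    The inhibition sums are updated with the *pre-step* ethanol
    concentration (exposure index runs over completed steps only).  Under
    ``inhibition="current"`` the deactivation constants of the supplied
    (current-temperature) parameter set are applied to the whole
    accumulated exposure; under ``"historical"`` each increment is weighted
    with the deactivation constant in force when it accrued.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eff = _effective_state(state, params, inhibition)
    mu, beta, v = current_rates(eff, params)
    pn = state.p**params.n
    increment = pn * dt
    s_p = state.s_p + increment
    if inhibition == "current":
        s_mu = params.k_prime * s_p
        s_beta = params.k_dprime * s_p
    else:
        s_mu = state.s_mu + params.k_prime * increment
        s_beta = state.s_beta + params.k_dprime * increment
    return FermentationState(
        t=state.t + dt,
        x=state.x + mu * state.x * dt,
        p=state.p + v * state.x * dt,
        s_mu=s_mu,
        s_beta=s_beta,
        s_p=s_p,
    )


@dataclass(frozen=True)
class Trajectory:
    """Time-indexed record of a simulation run (uniform grid, t=0 included).

    ``mu``/``beta``/``v`` at each record are the specific rates used to
    advance from that record; the final record carries the rates evaluated
    at the final state.
    """

    time_h: np.ndarray
    temp_C: np.ndarray
    cellmass_gL: np.ndarray
    ethanol_gL: np.ndarray
    mu_per_h: np.ndarray
    beta_per_h: np.ndarray
    v_per_h: np.ndarray

    COLUMNS = (
        "time_h",
        "temp_C",
        "cellmass_gL",
        "ethanol_gL",
        "mu_per_h",
        "beta_per_h",
        "v_per_h",
    )

    def __len__(self) -> int:
        return len(self.time_h)

    @property
    def final_time(self) -> float:
        return float(self.time_h[-1])

    @property
    def final_cellmass(self) -> float:
        return float(self.cellmass_gL[-1])

    @property
    def final_ethanol(self) -> float:
        return float(self.ethanol_gL[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in self.COLUMNS})

    def validate(self) -> None:
        """Check trajectory invariants; raises ``ValueError`` on violation."""
        dt = np.diff(self.time_h)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid is not uniform")
        if len(dt) and dt[0] <= 0:
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(self.cellmass_gL) < 0) or np.any(
            np.diff(self.ethanol_gL) < 0
        ):
            raise ValueError("cell mass and ethanol must be non-decreasing")
        if np.any(self.mu_per_h <= 0) or np.any(self.beta_per_h <= 0):
            raise ValueError("specific rates must be positive")


def simulate(
    schedule: Callable[[float], float],
    t_total: float,
    *,
    x0: float = 0.1,
    p0: float = 0.0,
    alpha: float = 2.2,
    n: float = 1.0,
    dt: float = 0.01,
    thermo: ThermoConstants = DEFAULT_THERMO,
    inhibition: str = "current",
) -> Trajectory:
    """Simulate a batch fermentation under a temperature schedule.

    ``schedule`` maps elapsed time (h) to temperature (deg C); any callable
    works, including :class:`fermkin.schedule.TemperatureSchedule`.  The
    kinetic parameter set is re-evaluated each step for variable schedules
    and once for constant schedules.  Returns a :class:`Trajectory` of
    ``m + 1`` records where ``m = t_total / dt``; a non-integer ratio is
    rounded up with a warning.
    """
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    if p0 < 0:
        raise ValueError("p0 must be non-negative")
    if t_total < 0:
        raise ValueError("t_total must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if inhibition not in ("current", "historical"):
        raise ValueError(f"unknown inhibition convention {inhibition!r}")

    ratio = t_total / dt
    m = int(round(ratio))
    if abs(ratio - m) > 1e-9 * max(1.0, ratio):
        m = math.ceil(ratio - 1e-12)
        warnings.warn(
            f"t_total={t_total} is not an integer multiple of dt={dt}; "
            f"simulating {m} steps to t={m * dt:g} h",
            stacklevel=2,
        )

    is_constant = getattr(schedule, "kind", None) == "constant"
    exp = math.exp
    t_arr = np.empty(m + 1)
    T_arr = np.empty(m + 1)
    x_arr = np.empty(m + 1)
    p_arr = np.empty(m + 1)
    mu_arr = np.empty(m + 1)
    beta_arr = np.empty(m + 1)

    x, p, s_p, s_mu, s_beta = x0, p0, 0.0, 0.0, 0.0
    current = inhibition == "current"
    if is_constant:
        T = float(schedule(0.0))
        par = kinetic_params_at(T, thermo, alpha, n)
        mu0, beta0, kp, kpp = par.mu0, par.beta0, par.k_prime, par.k_dprime
    for i in range(m + 1):
        t = i * dt
        if not is_constant:
            T = float(schedule(t))
            par = kinetic_params_at(T, thermo, alpha, n)
            mu0, beta0, kp, kpp = par.mu0, par.beta0, par.k_prime, par.k_dprime
        if current:
            s_mu = kp * s_p
            s_beta = kpp * s_p
        mu = mu0 * exp(-s_mu)
        beta = beta0 * exp(-s_beta)
        t_arr[i], T_arr[i] = t, T
        x_arr[i], p_arr[i] = x, p
        mu_arr[i], beta_arr[i] = mu, beta
        if i == m:
            break
        # Euler update; exposure increment uses the pre-step ethanol.
        inc = p**n * dt
        x += mu * x * dt
        p += (alpha * mu + beta) * x_arr[i] * dt
        s_p += inc
        if not current:
            s_mu += kp * inc
            s_beta += kpp * inc

    return Trajectory(
        time_h=t_arr,
        temp_C=T_arr,
        cellmass_gL=x_arr,
        ethanol_gL=p_arr,
        mu_per_h=mu_arr,
        beta_per_h=beta_arr,
        v_per_h=alpha * mu_arr + beta_arr,
    )
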