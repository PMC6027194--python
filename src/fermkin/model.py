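"""Model / results objects for batch fermentation simulation and calibration.

:class:`BatchFermentationModel` bundles the kinetic constants of one
fermentation (thermodynamic Arrhenius set, growth-associated yield
``alpha``, inhibition degree ``n``, pitch ``x0``) with the numerical
settings, exposes :meth:`~BatchFermentationModel.simulate`, and fits the
constants the Arrhenius table does not cover — ``alpha``, ``n`` and the
pitching rate ``x0`` — to observed final concentrations via
:meth:`~BatchFermentationModel.fit`, which returns a
:class:`CalibrationResults` carrying estimates, standard errors, residuals
and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import SimulationConfig
from .kinetics import DEFAULT_THERMO, ThermoConstants, Trajectory, simulate
from .schedule import TemperatureSchedule

__all__ = ["BatchFermentationModel", "CalibrationResults", "CALIBRATED_PARAMS"]

#: Constants fitted to the full set of published fixed-temperature final
#: concentrations (20-40 degC at 24 h and 60 h); see docs/methods.md.
#: Regenerate with ``BatchFermentationModel().fit(all_temperature_targets())``.
CALIBRATED_PARAMS = {"alpha": 3.66628, "n": 0.99278, "x0": 0.29194}

_FIT_BOUNDS = {"alpha": (0.0, 20.0), "n": (0.25, 4.0), "x0": (0.001, 10.0)}


class BatchFermentationModel:
    """Batch ethanol fermentation model for *S. cerevisiae* on corn mash.

    Parameters
    ----------
    alpha : growth-associated yield (g ethanol / g cell mass).
    n : ethanol inhibition degree (dimensionless exponent).
    x0 : initial cell mass concentration, i.e. yeast pitch (g/L).
    p0 : initial ethanol concentration (g/L).
    dt : Euler time step (h).
    thermo : Arrhenius constants for mu0, k', beta0, k''.
    inhibition : ``"current"`` (deactivation constants of the current
        temperature applied to the accumulated ethanol exposure; rates
        rebound when the batch cools) or ``"historical"`` (each exposure
        increment permanently weighted at the temperature it accrued).
    """

    def __init__(
        self,
        alpha: float = 2.2,
        n: float = 1.0,
        x0: float = 0.1,
        p0: float = 0.0,
        dt: float = 0.01,
        thermo: ThermoConstants = DEFAULT_THERMO,
        inhibition: str = "current",
    ) -> None:
        self.alpha = float(alpha)
        self.n = float(n)
        self.x0 = float(x0)
        self.p0 = float(p0)
        self.dt = float(dt)
        self.thermo = thermo
        self.inhibition = inhibition

    @classmethod
    def from_config(cls, config: SimulationConfig) -> "BatchFermentationModel":
        return cls(
            alpha=config.alpha,
            n=config.n,
            x0=config.x0,
            p0=config.p0,
            dt=config.dt,
            thermo=config.thermo,
            inhibition=config.inhibition,
        )

    @classmethod
    def calibrated(cls, **overrides) -> "BatchFermentationModel":
        """Model with the shipped calibrated {alpha, n, x0}."""
        kwargs = dict(CALIBRATED_PARAMS)
        kwargs.update(overrides)
        return cls(**kwargs)

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(alpha={self.alpha:g}, n={self.n:g}, "
            f"x0={self.x0:g}, p0={self.p0:g}, dt={self.dt:g}, "
            f"inhibition={self.inhibition!r})"
        )

    def simulate(
        self,
        schedule: TemperatureSchedule,
        t_total: float,
        dt: float | None = None,
        x0: float | None = None,
    ) -> Trajectory:
        """Run the model under ``schedule`` for ``t_total`` hours."""
        return simulate(
            schedule,
            t_total,
            x0=self.x0 if x0 is None else x0,
            p0=self.p0,
            alpha=self.alpha,
            n=self.n,
            dt=self.dt if dt is None else dt,
            thermo=self.thermo,
            inhibition=self.inhibition,
        )

    def final_values(
        self, schedule: TemperatureSchedule, t_total: float, **kw
    ) -> tuple[float, float]:
        """Final ``(cell mass, ethanol)`` in g/L."""
        traj = self.simulate(schedule, t_total, **kw)
        return traj.final_cellmass, traj.final_ethanol

    # ------------------------------------------------------------------
    # calibration

    def _residuals(
        self, theta: np.ndarray, free: Sequence[str], targets: pd.DataFrame
    ) -> np.ndarray:
        values = {name: val for name, val in zip(free, theta)}
        alpha = values.get("alpha", self.alpha)
        n = values.get("n", self.n)
        x0 = values.get("x0", self.x0)
        res = []
        for row in targets.itertuples():
            traj = simulate(
                TemperatureSchedule.constant(row.temp_C),
                row.t_total_h,
                x0=x0,
                p0=self.p0,
                alpha=alpha,
                n=n,
                dt=self.dt,
                thermo=self.thermo,
                inhibition=self.inhibition,
            )
            res.append((traj.final_cellmass - row.cellmass_gL) / row.cellmass_gL)
            res.append((traj.final_ethanol - row.ethanol_gL) / row.ethanol_gL)
        return np.asarray(res)

    def fit(
        self,
        targets: pd.DataFrame | None = None,
        free: Sequence[str] = ("alpha", "n", "x0"),
        start: Sequence[float] | None = None,
    ) -> "CalibrationResults":
        """Fit the free constants to observed final concentrations.

        ``targets`` must have columns ``temp_C, t_total_h, cellmass_gL,
        ethanol_gL`` (one constant-temperature batch per row); it defaults
        to the published 60-h fixed-temperature final values.  The loss is
        the sum of squared *relative* errors of both final concentrations,
        minimised with bounded trust-region least squares from a fixed
        deterministic start, so repeated fits are bit-identical.
        """
        if targets is None:
            from .experiments import fixed_temperature_targets

            targets = fixed_temperature_targets()
        unknown = set(free) - set(_FIT_BOUNDS)
        if unknown:
            raise ValueError(f"cannot fit parameter(s): {sorted(unknown)}")
        if start is None:
            start = [getattr(self, name) for name in free]
        lo = [_FIT_BOUNDS[name][0] for name in free]
        hi = [_FIT_BOUNDS[name][1] for name in free]
        start = np.clip(start, lo, hi)
        sol = least_squares(
            self._residuals,
            start,
            bounds=(lo, hi),
            args=(tuple(free), targets),
            xtol=1e-12,
            ftol=1e-14,
            gtol=1e-12,
        )
        if not sol.success:
            import warnings

            warnings.warn(
                f"calibration did not fully converge: {sol.message}; "
                "reporting best-found parameters",
                stacklevel=2,
            )
        params = pd.Series(sol.x, index=list(free), name="estimate")
        bse = _standard_errors(sol, len(free))
        fitted_model = BatchFermentationModel(
            alpha=params.get("alpha", self.alpha),
            n=params.get("n", self.n),
            x0=params.get("x0", self.x0),
            p0=self.p0,
            dt=self.dt,
            thermo=self.thermo,
            inhibition=self.inhibition,
        )
        resid = targets.copy()
        sim_x, sim_p = [], []
        for row in targets.itertuples():
            x, p = fitted_model.final_values(
                TemperatureSchedule.constant(row.temp_C), row.t_total_h
            )
            sim_x.append(x)
            sim_p.append(p)
        resid["sim_cellmass_gL"] = sim_x
        resid["sim_ethanol_gL"] = sim_p
        resid["rel_err_cellmass"] = (
            resid.sim_cellmass_gL - resid.cellmass_gL
        ) / resid.cellmass_gL
        resid["rel_err_ethanol"] = (
            resid.sim_ethanol_gL - resid.ethanol_gL
        ) / resid.ethanol_gL
        return CalibrationResults(
            model=fitted_model,
            params=params,
            bse=pd.Series(bse, index=list(free), name="std err"),
            residuals=resid,
            cost=float(sol.cost),
            success=bool(sol.success),
            message=str(sol.message),
            nfev=int(sol.nfev),
        )


def _standard_errors(sol, k: int) -> np.ndarray:
    """Gauss-Newton standard errors from the least-squares Jacobian."""
    m = len(sol.fun)
    dof = max(m - k, 1)
    sigma2 = 2.0 * sol.cost / dof
    try:
        JTJ = sol.jac.T @ sol.jac
        cov = sigma2 * np.linalg.pinv(JTJ)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(k, np.nan)


@dataclass
class CalibrationResults:
    """Fitted constants with uncertainties and per-condition diagnostics."""

    model: BatchFermentationModel
    params: pd.Series
    bse: pd.Series
    residuals: pd.DataFrame
    cost: float
    success: bool
    message: str
    nfev: int

    @property
    def rmse_relative(self) -> float:
        """Root-mean-square relative error over all fitted final values."""
        r = np.concatenate(
            [self.residuals.rel_err_cellmass, self.residuals.rel_err_ethanol]
        )
        return float(np.sqrt(np.mean(r**2)))

    def summary(self) -> str:
        lines = [
            "Batch fermentation calibration",
            "=" * 58,
            f"observations (final values): {2 * len(self.residuals)}",
            f"converged: {self.success}   nfev: {self.nfev}",
            f"rms relative error: {self.rmse_relative:.4f}",
            "-" * 58,
            f"{'parameter':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<10}{self.params[name]:>14.5g}{self.bse[name]:>14.3g}"
            )
        lines.append("-" * 58)
        lines.append("per-condition relative errors (cell mass / ethanol):")
        for row in self.residuals.itertuples():
            lines.append(
                f"  {row.temp_C:>5.1f} degC, {row.t_total_h:>5.1f} h: "
                f"{row.rel_err_cellmass:+7.2%} / {row.rel_err_ethanol:+7.2%}"
            )
        return "\n".join(lines)
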