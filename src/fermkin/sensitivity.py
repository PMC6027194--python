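"""Parametric sensitivity analysis: LHS design, GP surrogate, Sobol indices.

The analysis screens three controllable batch inputs — yeast pitch (g/L),
fermentation temperature (degC, held constant per batch) and fermentation
time (h) — for their influence on two responses: total ethanol produced
(g/L) and mean production rate (final ethanol divided by fermentation
time, g/(L h)).

A Latin hypercube design over the factor box is evaluated with the full
simulator, an anisotropic Gaussian-process surrogate is fitted to each
response, and variance-based main-effect (first-order) and total Sobol
indices are estimated by Saltelli/Jansen Monte-Carlo over the surrogate
mean with uniform factor distributions.  The raw index estimates are
projected onto the feasible region ``0 <= main <= total <= 1``, which
holds exactly for the true indices and can be violated by a few percent of
Monte-Carlo/surrogate noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .model import BatchFermentationModel
from .schedule import TemperatureSchedule

__all__ = [
    "FactorRange",
    "DEFAULT_FACTORS",
    "DesignMatrix",
    "lhs_design",
    "evaluate_design",
    "GPSurrogate",
    "fit_surrogate",
    "effect_indices",
    "SensitivityResult",
    "run_sensitivity_analysis",
]

RESPONSES = ("total_production_gL", "production_rate_gL_per_h")


@dataclass(frozen=True)
class FactorRange:
    """One factor of the sensitivity design with its bounds."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"degenerate range for {self.name!r}: "
                f"[{self.lower}, {self.upper}]"
            )


#: Screening box: pitch 0-10 g/L, temperature 20-40 degC, time 12-90 h.
DEFAULT_FACTORS = (
    FactorRange("yeast_gL", 0.0, 10.0),
    FactorRange("temp_C", 20.0, 40.0),
    FactorRange("time_h", 12.0, 90.0),
)


@dataclass(frozen=True)
class DesignMatrix:
    """Latin hypercube design: one sample per equal-width stratum per factor."""

    points: np.ndarray
    factors: tuple[FactorRange, ...]
    seed: int

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=[f.name for f in self.factors])

    def unit_points(self) -> np.ndarray:
        lo = np.array([f.lower for f in self.factors])
        hi = np.array([f.upper for f in self.factors])
        return (self.points - lo) / (hi - lo)


def lhs_design(
    ranges: tuple[FactorRange, ...] = DEFAULT_FACTORS,
    n_points: int = 100,
    seed: int = 0,
) -> DesignMatrix:
    """Seeded Latin hypercube sample scaled to the factor bounds."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    ranges = tuple(ranges)
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    unit = sampler.random(n_points)
    lo = [f.lower for f in ranges]
    hi = [f.upper for f in ranges]
    return DesignMatrix(points=qmc.scale(unit, lo, hi), factors=ranges, seed=seed)


def evaluate_design(
    design: DesignMatrix,
    model: BatchFermentationModel | None = None,
) -> pd.DataFrame:
    """Run the simulator at every design point.

    Factor semantics: yeast concentration is the initial cell mass ``x0``,
    temperature is held constant for the run, time is the horizon.  Design
    runs start ethanol-free.  A zero-pitch point yields exactly zero for
    both responses (both state derivatives scale with ``x``).
    """
    model = model or BatchFermentationModel.calibrated()
    names = [f.name for f in design.factors]
    expected = [f.name for f in DEFAULT_FACTORS]
    if names != expected:
        raise ValueError(f"expected factors {expected}, got {names}")
    out = design.to_frame()
    prod = np.empty(design.n_points)
    for i, (yeast, temp, t_total) in enumerate(design.points):
        if yeast <= 0.0:
            prod[i] = 0.0
            continue
        # snap the horizon onto the Euler grid to avoid rounding warnings
        t_snap = max(round(t_total / model.dt), 1) * model.dt
        traj = model.simulate(
            TemperatureSchedule.constant(temp), t_snap, x0=yeast
        )
        prod[i] = traj.final_ethanol
    out[RESPONSES[0]] = prod
    out[RESPONSES[1]] = prod / out["time_h"]
    return out


@dataclass
class GPSurrogate:
    """Gaussian-process response surface on the unit-cube factor space."""

    gp: GaussianProcessRegressor
    factors: tuple[FactorRange, ...]
    X_unit: np.ndarray
    y: np.ndarray

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Posterior-mean prediction at ``points`` in *factor* units."""
        lo = np.array([f.lower for f in self.factors])
        hi = np.array([f.upper for f in self.factors])
        return self.gp.predict((np.atleast_2d(points) - lo) / (hi - lo))

    def loo_correlation(self) -> float:
        """Leave-one-out prediction/actual correlation, with the kernel
        hyperparameters frozen at their full-data optimum."""
        kernel = self.gp.kernel_
        n = len(self.y)
        preds = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            gp_i = GaussianProcessRegressor(
                kernel=kernel, optimizer=None, normalize_y=True
            )
            gp_i.fit(self.X_unit[mask], self.y[mask])
            preds[i] = gp_i.predict(self.X_unit[i : i + 1])[0]
        return float(np.corrcoef(preds, self.y)[0, 1])


def fit_surrogate(
    design: DesignMatrix,
    responses: np.ndarray | pd.Series,
    seed: int = 0,
) -> GPSurrogate:
    """Fit an anisotropic RBF Gaussian process to one response column.

    Inputs are rescaled to the unit cube; per-factor length scales let the
    response correlation decay at a different rate along each factor; a
    small fitted nugget absorbs the Euler-discretisation roughness.
    """
    y = np.asarray(responses, dtype=float)
    if design.n_points < 10:
        raise ValueError("need at least 10 design points to fit a surrogate")
    if len(y) != design.n_points:
        raise ValueError("response length does not match design")
    X = design.unit_points()
    for j, f in enumerate(design.factors):
        if np.ptp(X[:, j]) < 1e-12:
            raise ValueError(
                f"rank-deficient design: factor {f.name!r} has no variation"
            )
    d = len(design.factors)
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF(length_scale=[0.3] * d, length_scale_bounds=(1e-2, 1e2))
        + WhiteKernel(1e-6, (1e-12, 1e0))
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=2,
        random_state=seed,
    )
    gp.fit(X, y)
    return GPSurrogate(gp=gp, factors=design.factors, X_unit=X, y=y)


def effect_indices(
    surrogate: GPSurrogate,
    ranges: tuple[FactorRange, ...] | None = None,
    n_mc: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Main-effect and total Sobol indices of each factor.

    Saltelli pick-freeze scheme over the surrogate mean with independent
    uniform factors: first-order ``S_i = E[f_B (f_ABi - f_A)] / V`` and
    total ``ST_i = E[(f_A - f_ABi)^2] / (2 V)`` (Jansen), followed by
    projection onto ``0 <= S_i <= ST_i <= 1``.

    Raises ``ValueError`` if the surrogate's response surface has (near)
    zero variance over the box, where the indices are undefined.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be at least 1000")
    ranges = tuple(ranges) if ranges is not None else surrogate.factors
    d = len(ranges)
    lo = np.array([f.lower for f in ranges])
    hi = np.array([f.upper for f in ranges])
    rng = np.random.default_rng(seed)
    A = lo + rng.uniform(size=(n_mc, d)) * (hi - lo)
    B = lo + rng.uniform(size=(n_mc, d)) * (hi - lo)
    fA = surrogate.predict(A)
    fB = surrogate.predict(B)
    V = np.var(np.concatenate([fA, fB]))
    scale = np.mean(np.abs(np.concatenate([fA, fB]))) + 1e-300
    if V / scale**2 < 1e-12:
        raise ValueError(
            "response variance is (near) zero over the factor box; "
            "sensitivity indices are undefined"
        )
    main = np.empty(d)
    total = np.empty(d)
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        fABi = surrogate.predict(ABi)
        main[i] = np.mean(fB * (fABi - fA)) / V
        total[i] = 0.5 * np.mean((fA - fABi) ** 2) / V
    main = np.clip(main, 0.0, 1.0)
    total = np.clip(total, 0.0, 1.0)
    total = np.maximum(total, main)
    return pd.DataFrame(
        {
            "factor": [f.name for f in ranges],
            "main_effect": main,
            "total_sensitivity": total,
        }
    )


@dataclass
class SensitivityResult:
    """Per-response Sobol indices plus surrogate fit quality."""

    design: pd.DataFrame
    indices: dict[str, pd.DataFrame]
    surrogate_quality: dict[str, float]
    seed: int

    def indices_table(self) -> pd.DataFrame:
        """All indices in one tidy frame (response, factor, main, total)."""
        frames = []
        for response, df in self.indices.items():
            df = df.copy()
            df.insert(0, "response", response)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def top_factor(self, response: str) -> str:
        df = self.indices[response]
        return str(df.loc[df.total_sensitivity.idxmax(), "factor"])


def run_sensitivity_analysis(
    model: BatchFermentationModel | None = None,
    ranges: tuple[FactorRange, ...] = DEFAULT_FACTORS,
    n_points: int = 100,
    n_mc: int = 10_000,
    seed: int = 0,
    loo: bool = False,
) -> SensitivityResult:
    """End-to-end analysis: design -> simulate -> surrogate -> indices."""
    model = model or BatchFermentationModel.calibrated()
    design = lhs_design(ranges, n_points=n_points, seed=seed)
    table = evaluate_design(design, model)
    indices = {}
    quality = {}
    for response in RESPONSES:
        surrogate = fit_surrogate(design, table[response], seed=seed)
        indices[response] = effect_indices(
            surrogate, ranges, n_mc=n_mc, seed=seed + 1
        )
        if loo:
            quality[response] = surrogate.loo_correlation()
    return SensitivityResult(
        design=table, indices=indices, surrogate_quality=quality, seed=seed
    )
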