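# Methods

## Model

The simulator implements a nonlinear batch-fermentation system for
*S. cerevisiae* on a glucose-replete corn mash. Cell mass `x` and ethanol
`p` (both g/L) evolve as `dx/dt = μx`, `dp/dt = (αμ + β)x`: production is
split Luedeking–Piret-style into a growth-associated part (coefficient
`α`, g ethanol per g new cell mass) and a non-growth-associated specific
rate `β` (h⁻¹). There is no substrate balance (glucose is assumed
non-limiting), no cell-death term (`dx/dt = μx ≥ 0`; apparent "decay" at
high temperature is rate decay, which the model reproduces as
plateauing), constant pH, and no contamination.

Ethanol stress deactivates both pathways through the accumulated exposure
`S = Σᵢ pᵢⁿ Δt` (the discrete analogue of `∫pⁿ dt`):
`μ = μ₀·e^(−k′S)` and `β = β₀·e^(−k″S)`, with inhibition degree `n`.
`μ₀, k′, β₀, k″` are Arrhenius functions `A·exp(−E/(R·T_K))` of absolute
temperature, with the shipped empirical constants

| parameter | A | E (cal/mol) |
|---|---|---|
| μ₀ | 8.84×10⁸ h⁻¹ | 1.30×10⁴ |
| k′ | 7.12×10¹⁴ L g⁻¹ h⁻¹ | 2.34×10⁴ |
| β₀ | 1.48×10⁷ h⁻¹ | 9.76×10³ |
| k″ | 1.76×10⁴ L g⁻¹ h⁻¹ | 1.00×10⁴ |

and R = 1.987 cal K⁻¹ mol⁻¹. The deactivation constants' printed units
are dimensionally exact for n = 1 (general n needs (L/g)ⁿ h⁻¹); we default
n = 1 and treat the units as nominal otherwise. Schedules operate in °C
(the exponential-decay law is defined on the numeric Celsius value — only
that convention reproduces the reference decay constants 0.0116 and
0.0289 h⁻¹ for 40→20 °C over 60 and 24 h); Kelvin conversion happens only
inside the Arrhenius evaluation, and a guard range of −20…80 °C rejects
physically implausible inputs.

## Inhibition memory under a changing temperature

With temperature varying, the model must decide how past ethanol exposure
interacts with the temperature-dependent deactivation constants. The
package implements two conventions:

- **current** (default): the deactivation constants of the *current*
  temperature weight the whole accumulated exposure,
  `μ(t) = μ₀(T)·exp(−k′(T)·Σpᵢⁿ∆t)`. Every kinetic parameter — including
  the sensitivity of the cell to its ethanol history — is re-evaluated at
  each step's temperature. Cooling therefore shrinks the inhibition
  exponent (k′ falls ~13-fold from 40 to 20 °C) and the specific rates
  partially rebound. This is the convention that reproduces the published
  controlled-cooling behaviour: at a 24-h horizon the 40→20 °C batch out-
  produces both fixed batches, and over 60 h the fixed 20 °C batch
  overtakes it at roughly 40 h.
- **historical**: each exposure increment is permanently weighted with the
  deactivation constant in force when it accrued,
  `μ(t) = μ₀(T)·exp(−Σ k′(Tᵢ)pᵢⁿ∆t)`; deactivation is irreversible. Under
  this convention a cooled batch can never overtake the constant-hot batch
  on a short horizon, contradicting the published 24-h ranking — it is
  retained as an option because it is the natural reading of
  "accumulated damage".

The two conventions coincide exactly at constant temperature, so all
fixed-temperature results (including calibration) are
convention-independent.

## Numerics

Explicit forward Euler advances the state on the same uniform grid that
accumulates the inhibition sum, matching the model's inherently discrete
product form; the exposure increment uses the pre-step ethanol
concentration. Default Δt = 0.01 h puts the discretisation error well
below the 3-significant-figure scale of the reported final values; the
test suite verifies observed convergence order ≈ 1 against an adaptive
LSODA solution (rtol 1e−11) of the equivalent ODE system
`dμ/dt = −k′pⁿμ`, `dβ/dt = −k″pⁿβ`, and exact agreement with the
closed-form exponential solution when k′ = k″ = 0. A horizon that is not
an integer multiple of Δt is rounded up to the next full step with a
warning. Algebraic identities are tested at relative tolerance 1e−9,
convergence checks at 1e−3. All arithmetic is double precision.

## Calibration

The Arrhenius table fixes four of the six constants; `α`, `n` and the
pitch `x0` must be estimated. `BatchFermentationModel.fit()` minimises
the sum of squared *relative* errors of final cell mass and final ethanol
over a table of constant-temperature batches, using bounded trust-region
least squares (`α ∈ [0, 20]`, `n ∈ [0.25, 4]`, `x0 ∈ [0.001, 10] g/L`)
from a fixed start, so fits are deterministic. Standard errors come from
the Gauss–Newton Jacobian. Self-consistency (targets generated by the
simulator are recovered to machine precision) is a tested property.

The default target table is the published 60-h fixed-temperature sweep
(20/26/33/40 °C). Those eight values alone leave `x0` weakly identified —
60-h finals are nearly flat in the pitch, and the optimizer drifts to
x0 ≈ 1 g/L, which contradicts the published 24-h fixed-temperature finals
(a 20 °C batch would be nearly finished at 24 h instead of halfway). The
*shipped* calibrated configuration (α = 3.666, n = 0.993,
x0 = 0.292 g/L) is therefore fitted to all twelve published
fixed-temperature finals (the 60-h sweep plus the 20 and 40 °C rows of
the 24-h/60-h strategy comparison, `all_temperature_targets()`); it
reproduces them with ≈2–12% relative error (rms ≈ 6%) and satisfies every
published qualitative ordering with margin. A single {α, n, x0} cannot
drive all twelve residuals to zero — the residual table quantifies the
remaining misfit, part of which traces to the source values themselves
(the same 20 °C/60 h condition is printed as 145.8 g/L in one table and
143.29 g/L in another).

## Sensitivity analysis

Three controllable inputs are screened over a box of pitch 0–10 g/L,
temperature 20–40 °C (constant per batch, ethanol-free start) and time
12–90 h, for two responses: final ethanol (g/L) and mean production rate
(final ethanol / time). The design is a seeded Latin hypercube (one
sample per equal-width stratum per factor; scipy's `qmc`). Each response
gets an anisotropic surrogate — a Gaussian process with
constant × RBF kernel, per-factor length scales, inputs rescaled to the
unit cube, `normalize_y`, and a fitted white-noise nugget for numerical
stability — so response correlation decays with distance at a per-factor
rate. Default design size is 100 points, ample for three factors;
leave-one-out correlation (hyperparameters frozen at the full-data
optimum) exceeds 0.99 on this problem.

Main-effect and total indices are Sobol variance decompositions estimated
on the surrogate *mean* by the Saltelli pick-freeze scheme with uniform
factors (default 10⁴ base samples): first-order
`Sᵢ = E[f_B(f_ABᵢ − f_A)]/V` and total `STᵢ = E[(f_A − f_ABᵢ)²]/(2V)`
(Jansen). True indices satisfy `0 ≤ Sᵢ ≤ STᵢ ≤ 1`; raw estimates can
violate this by a few hundredths of Monte-Carlo/surrogate noise, so
estimates are projected onto that region (clip to [0, 1], then
`STᵢ ← max(STᵢ, Sᵢ)`). The factor *ranking* — pitch dominant for total
production, time dominant for rate, temperature minor — is stable across
seeds and is what the acceptance checks assert; exact magnitudes vary at
the few-percent level with the design and MC seed. A zero-pitch design
point short-circuits to exactly zero response (both derivatives scale
with `x`), and a response surface with (near-)zero variance over the box
raises instead of returning undefined indices.

## What the built-in scenarios do and do not show

The experiment suites simulate the published scenarios (fixed 20–40 °C
sweep at 60 h; fixed vs exponentially cooled batches at 24-h and 60-h
horizons) and check their qualitative structure: monotone decrease of
both finals with temperature, the horizon-dependent ranking of the
cooling strategy, and the existence of a crossover where the 20 °C batch
overtakes the cooled one before 60 h. Absolute simulated finals depend on
the calibrated {α, n, x0} and are reported as calibration residuals, not
asserted as constants. Percentage comparisons mirror two distinct
published conventions — difference over the *subject* value for strategy
comparisons, difference over the *simulated* value for the external
validation table — implemented as separate documented operations; the
external SSF datasets behind the validation table are compared only
through their printed final values, not re-digitised time courses. All of
this exercises an idealised batch: perfectly mixed, pH-controlled,
contamination-free, substrate-unlimited. Passing checks show the
implementation reproduces the model's documented behaviour, not that the
model predicts any particular real fermentor.

## Known limitations

- Forward Euler is first-order; halving Δt halves the error. The default
  grid is adequate for the shipped scenarios but stiff parameter choices
  (very large k′pⁿ) warrant a smaller step.
- The inhibition-memory question is genuinely underdetermined by the
  model's discrete product form; both conventions are provided, and only
  constant-temperature conclusions are convention-free.
- `x0` calibrated from 60-h finals alone is practically unidentifiable;
  include short-horizon observations (as the shipped calibration does)
  when fitting the pitch.
- Sobol indices are computed on the GP mean, so surrogate bias (not just
  MC noise) enters the estimates; the LOO correlation is reported as the
  fit-quality guard.
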