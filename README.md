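# fermkin

Kinetic simulation of batch ethanol fermentation of corn mash by
*Saccharomyces cerevisiae*, with Arrhenius temperature dependence of all
kinetic constants, controlled variable-temperature schedules, and a
Gaussian-process-based parametric sensitivity analysis.

It is aimed at bioprocess engineers and instructors who want to explore
how fermentation temperature — fixed, or deliberately decreased during the
batch — trades off initial productivity against ethanol stress, without
running a fermentor.

## The model

Two state variables, cell mass `x` (g/L) and ethanol `p` (g/L):

```
dx/dt = μ x
dp/dt = (α μ + β) x
```

Production follows the Luedeking–Piret decomposition: `α` (g ethanol per g
new cell mass) couples production to growth, `β` (h⁻¹) is the
non-growth-associated specific rate (maintenance and energy-uncoupling
terms). Both specific rates decay with the accumulated ethanol exposure

```
μ = μ₀ exp(−k′ S),   β = β₀ exp(−k″ S),   S = Σᵢ pᵢⁿ Δt
```

with inhibition degree `n` and deactivation constants `k′`, `k″`. The
four constants `μ₀, k′, β₀, k″` each obey an Arrhenius law
`A·exp(−E/(R·T))` (R = 1.987 cal K⁻¹ mol⁻¹) with empirical frequency
factors and activation energies shipped as defaults, so warm batches start
fast but also self-inhibit fast. Temperature schedules are either constant
or an exponential cooling `T(t) = T₀·e^(−ct)` whose decay constant
`c = −ln(Tf/T₀)/t_total` reaches `Tf` exactly at the horizon.

State is advanced by forward Euler on the same grid that accumulates the
inhibition sum (Δt = 0.01 h by default); first-order convergence to the
equivalent ODE system is part of the test suite. Under the default
convention the current temperature's `k′(T), k″(T)` weight the whole
accumulated exposure, so cooling a batch lets the specific rates rebound;
`inhibition="historical"` freezes each increment at the temperature at
which it accrued (both coincide for constant-temperature runs). The
growth-associated yield `α`, inhibition degree `n` and yeast pitch `x0`
are not covered by the Arrhenius table; the package ships a calibrated set
(`BatchFermentationModel.calibrated()`) fitted to published
fixed-temperature final concentrations, and `fit()` re-estimates them from
any final-value table.

## Worked example

```python
from fermkin import BatchFermentationModel, TemperatureSchedule

model = BatchFermentationModel.calibrated()
cool = TemperatureSchedule.exponential(40.0, 20.0, 60.0)
print(f"decay constant c = {cool.c:.4f} 1/h")

traj = model.simulate(cool, 60.0)
print(f"controlled 40->20 degC, 60 h: x = {traj.final_cellmass:.2f} g/L, "
      f"p = {traj.final_ethanol:.1f} g/L")
for T in (20.0, 40.0):
    x, p = model.final_values(TemperatureSchedule.constant(T), 60.0)
    print(f"constant {T:g} degC, 60 h:      x = {x:.2f} g/L, p = {p:.1f} g/L")
```

prints

```
decay constant c = 0.0116 1/h
controlled 40->20 degC, 60 h: x = 4.50 g/L, p = 117.9 g/L
constant 20 degC, 60 h:      x = 9.03 g/L, p = 146.9 g/L
constant 40 degC, 60 h:      x = 3.97 g/L, p = 100.8 g/L
```

The cooled batch beats the constant 40 °C batch over 60 h (117.9 vs
100.8 g/L): it inherits the hot start, then sheds ethanol stress as it
cools. The steady 20 °C batch still wins the long game (146.9 g/L) — at
24 h the ranking is reversed, with the controlled batch ahead of both.
Calibration is a statsmodels-style fit:

```python
res = BatchFermentationModel().fit()   # defaults to the published 60-h finals
print(res.summary())                   # estimates, std errs, per-condition errors
```

A `fermkin` console script exposes the same functionality
(`simulate`, `schedule`, `sensitivity`, `reproduce`, `calibrate`);
run `fermkin --help`. Config files are flat YAML with dotted keys
(`x0`, `alpha`, `n`, `dt`, `t_total`, `schedule.kind`, `schedule.T0`,
`schedule.Tf`, `schedule.c`, `thermo.A1` … `thermo.E4`); defaults are
α = 2.2, n = 1, x0 = 0.1 g/L, p0 = 0 g/L, Δt = 0.01 h.

## Sensitivity analysis

`run_sensitivity_analysis()` screens yeast pitch (0–10 g/L), temperature
(20–40 °C) and time (12–90 h) with a Latin hypercube design, fits an
anisotropic RBF Gaussian process to total ethanol production and to mean
production rate (final ethanol / time), and estimates variance-based
main-effect and total Sobol indices over the surrogate. Yeast pitch
dominates total production; fermentation time dominates the production
rate; temperature contributes little over this box.

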