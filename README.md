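# moxiopt

Bioheat simulation and interval uncertainty optimization of mild-moxibustion
operating parameters.

## The problem

Mild moxibustion warms an acupoint by holding a burning moxa (mugwort) stick
a few centimetres above the skin. Its thermal dose is controlled by four
operating parameters — the maximum burning temperature of the stick
*t₁* (600–650 °C), the stick diameter *d* (12–18 mm), the stick-to-skin
distance *h* (25–35 mm) and the patient's skin moisture content
*ω_c* (29–52 %) — none of which a practitioner can hold exactly. Two
indicators summarize a treatment: the skin-surface temperature **ST**, which
must stay below the 45.5 °C comfort/safety allowable, and the thermal
penetration **HPM**, the temperature 5 mm below the surface, which measures
efficacy and should be as high as possible.

`moxiopt` treats each operating parameter as a closed interval
*d^I = [d^c − d^ω, d^c + d^ω]* (midpoint ± radius, no distributional
assumption) and answers two questions:

1. **Uncertainty analysis** — given the parameter intervals, what interval do
   ST and HPM fall in, and can ST exceed the allowable?
2. **Reliability-based optimization** — which interval midpoints maximize
   HPM while guaranteeing, at a chosen reliability level λ, that ST stays
   below the allowable *b* = 45.5 °C?

## The model chain

* **Bioheat simulator** (`moxiopt.bioheat`): axisymmetric transient Pennes
  equation ρc ∂T/∂t = ∇·(k∇T) + ω_b ρ_b C_b (T_b − T) + q_m over a
  three-layer tissue column (skin 2.2 mm / fat 12.4 mm / muscle 10.4 mm),
  with moisture-dependent skin properties and the radiative flux from the
  glowing moxa tip (harmonic tip temperature, disk view factor, gray
  exchange with the surroundings) as the surface boundary condition.
  Finite-volume in (r, z), backward Euler in time.
* **Surrogate** (`moxiopt.doe`): maximin Latin-hypercube sampling of the
  4-parameter domain, one simulation per point, and a Gaussian RBF network
  (with affine tail) per indicator; accuracy reported as RE range, RMSE and
  R² = 1 − SSE/SST on training and held-out points.
* **Interval propagation** (`moxiopt.uq`): response intervals
  [min f, max f] over a parameter box by multistart bounded local
  optimization, cross-checked by a tensor-grid oracle.
* **Interval optimization** (`moxiopt.interval_opt`): the reliability-based
  possibility degree of interval (RPDI)
  pr(A ≤ B) = (Bᴿ − Aᴸ)/(2Aʷ + 2Bʷ) turns the interval constraint
  S(d^I) ≤ b into the scalar condition (b − Sᴸ)/(2Sʷ) ≥ λ, so the program
  becomes deterministic in the midpoints and is solved by a nested scheme:
  a real-coded GA outside, interval-bound evaluations inside.

`moxiopt.synthetic` supplies closed-form pseudo-simulators and toy interval
programs with algebraic optima for validation; `moxiopt.pipeline` and the
`moxiopt` CLI chain everything end to end.

## Worked example

Full pipeline on the reduced-fidelity PDE backend (≈3 min on one CPU):

```bash
moxiopt run --seed 42 --out results/
```

which prints (numbers from an actual run):

```
Surrogate accuracy:
  training   HPM  RE [-0.000%, +0.000%]  R^2 = 1.0000
  training   ST   RE [-0.000%, +0.000%]  R^2 = 1.0000
  validation HPM  RE [-0.096%, +0.165%]  R^2 = 0.9998
  validation ST   RE [-0.167%, +0.580%]  R^2 = 0.9995
Uncertainty over the design domain: ST [41.99, 67.92] degC, HPM [39.29, 48.88] degC -> UNRELIABLE (allowable 45.5 degC, RPDI 0.135)
Optimal solutions by reliability level:
 lambda  ST_lo  ST_hi  HPM_lo  HPM_hi  achieved_rpdi  feasible
  0.800 44.074 45.856  39.904  40.573          0.800      True
  0.900 43.899 45.678  39.828  40.496          0.900      True
  1.000 43.763 45.500  39.764  40.412          1.000      True
  1.100 43.593 45.327  39.691  40.337          1.100      True
```

Reading the output: the surrogate reproduces held-out simulations to
R² ≥ 0.999; across the full operating domain ST can reach ≈68 °C, far above
the 45.5 °C allowable, so an *unoptimized* treatment is unreliable. The
reliability-constrained optimization then picks interval midpoints whose ST
interval upper bound sits exactly at the allowable for λ = 1.0 (the active
constraint) and below it for λ = 1.1, while HPM — the efficacy objective —
decreases as λ grows: buying reliability costs penetration.

Individual stages are available as subcommands (`simulate`,
`single-factor`, `doe`, `evaluate`, `train`, `uq`, `optimize`, `sweep`,
`report`, `fixtures`); run `moxiopt <cmd> --help`.

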