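# Methods

This note records the model, the numerical choices, the defaults and their
rationale, and what the synthetic stand-ins do and do not establish.

## Bioheat model

Tissue is a cylinder of radius 40 mm and depth 25 mm, axisymmetric about the
moxibustion axis, with z = 0 at the skin surface increasing downward. Three
horizontal layers: skin (2.2 mm), fat (12.4 mm), muscle (10.4 mm). Each
layer obeys the Pennes equation

ρc ∂T/∂t = ∇·(k∇T) + ω_b ρ_b C_b (T_b − T) + q_m

with T_b = 37 °C the arterial (core) temperature, ρ_b = 1060 kg m⁻³,
C_b = 3770 J kg⁻¹ K⁻¹ and q_m = 420 W m⁻³ metabolic heating. Fat and muscle
use fixed constants (fat: 911 kg m⁻³, 2348 J kg⁻¹ K⁻¹, 0.21 W m⁻¹ K⁻¹;
muscle: 1090, 3421, 0.49); the skin layer's ρ, c, k are functions of the
moisture fraction ω_c:

- ρ = (1.3 − 0.3 ω_c) g cm⁻³
- c = 4.19 (0.37 + 0.67 ω_c/ρ) kJ kg⁻¹ K⁻¹  (ρ in g cm⁻³)
- k = 0.419 (0.133 + 1.36 ω_c/ρ) W m⁻¹ K⁻¹

These fits reproduce the standard tabulated values at 29/40/52 % moisture to
printed precision; the only discrepancy is k at 52 % (formula 0.315 vs the
tabulated 0.32), which we treat as a rounding artifact and tolerate at
±0.01 in tests. Note the tabulated values, not the raw formulas, are the
normative oracle: the published formula text is dimensionally inconsistent
as printed and was reconciled to the table (ω_c/ρ with ρ in g cm⁻³ and a
×0.1 scale on k).

Moisture is carried in **percent** in tables, configs and the CLI (matching
how parameter levels are tabulated) and converted to a fraction exactly
once, at the simulator boundary.

### The moxa source

The burning tip is a hemisphere of diameter d whose surface temperature
follows the harmonic T_a(t) = (t₁ + T_floor)/2 + (t₁ − T_floor)/2 ·
cos(2πt/τ) with floor 200 °C and period τ = 500 s — the burn / ash-gather
cycle (defaults give 400 + 200 cos(2πt/500)). An optional "ash dip"
modifier (drop to 50 °C for 2 s every 60 s, emulating ash cleaning) exists
but is off by default because the harmonic already encodes the cyclic
cooling; enabling both would double-count it.

Radiation reaching a skin element at radius r is computed through the view
factor F(r) to the tip's great-circle disk. Because h is the gap between
the *closest point* of the glowing tip and the skin, that disk sits at
height h + d/2. F is evaluated by 64-node Gauss–Legendre quadrature of the
diffuse kernel (the azimuthal integral is closed-form); on axis it reduces
to R²/(R² + h_eff²), which serves as the test oracle. The net surface flux
is gray two-term exchange:

q(r) = ε_skin σ [ ε_tip F(r) (T_a⁴ − T_s⁴) + (1 − F(r)) (T_amb⁴ − T_s⁴) ]

with ε_skin = 0.95, ε_tip = 0.85 (ash-covered ember) and surroundings at
25 °C. The ambient term is what keeps the heated spot localized — without
it the whole surface integrates the source flux and the model runs far too
hot. Convective cooling is deliberately excluded (the tip is a
high-temperature radiative source and the model's scope excludes forced
air flow); radiative exchange with the room partially plays its role.

### Unstated physiological constants

Blood perfusion is layer-wise: skin 2×10⁻³ s⁻¹ (vasodilated, heated skin),
fat 5×10⁻⁴ s⁻¹, muscle 1×10⁻³ s⁻¹ — literature-typical values, all
configurable. Together with the source geometry and emissivities above,
these were fixed once by requiring the simulator to land on the published
indicator scale at the operating-domain centre (ST ≈ 45–52 °C, inside the
published [39.5, 58.1] °C envelope) and were not revisited afterwards. The
resulting corner-to-corner ST span is ≈43–70 °C: hotter overall than the
published ≈39.5–58.1 °C, but straddling the 45.5 °C allowable the same way,
which is the property every downstream conclusion depends on.

### Discretization

Cell-centred finite volumes: uniform Δr; per-layer uniform Δz chosen so
every layer boundary falls exactly on a cell face and every layer has ≥3
cells. Conductances use harmonic (series-resistance) averaging across
faces. Boundaries: prescribed flux on top, fixed T_b at the bottom
(half-cell resistance), zero flux on the axis and outer radius. Time
integration is backward Euler with the constant system matrix factorized
once (sparse LU); the T⁴ surface nonlinearity is lagged and converged by
fixed-point iteration to 10⁻⁶ °C per step (typically 2–3 iterations —
the radiative coefficient 4εσT³F is tiny next to conduction).

Because the grid is cell-centred, the z = 0 surface temperature is
reconstructed flux-consistently as T_cell0 + q Δz/(2k); without this the
read-out would be biased by half a cell and grid-refinement checks would
fail. ST is the maximum over the treatment window of the on-axis surface
temperature and HPM the maximum of the on-axis temperature at 5 mm depth
(linear interpolation between bracketing cell centres); the curves plateau
by ~13 min so the maximum essentially equals the final value.

Two presets: `fine` (Δr = Δz = 0.5 mm, Δt = 1 s) and `coarse`
(Δr ≈ 1 mm, Δz ≈ 0.7 mm after layer fitting, Δt = 2 s), both 1200 s.
Halving the coarse spacings and step moves ST and HPM by <0.1 °C, so the
coarse preset is used for surrogate training (~0.3 s per run). Verified
against (a) the 1-D semi-infinite constant-flux closed form
ΔT_s = 2q√(αt/π)/k to <2 % and (b) an independent explicit-Euler
integration of the same discretization to <0.05 °C.

## Design of experiments and surrogate

Latin hypercube over (t₁, d, h, ω_c) ∈ [600,650]×[12,18]×[25,35]×[29,52]:
one point per equal-probability stratum per dimension, best of 100 random
candidates under the maximin-distance criterion (the common reading of an
"optimal" LHS), fully seeded. 50 training and 20 validation points.

Each indicator gets a Gaussian RBF network on unit-cube-scaled inputs:
centres at the training points, width = median pairwise distance, weights
by a linear solve, optional ridge. The network is augmented with an affine
(constant + linear) tail fitted through the standard saddle-point system;
the indicators are dominantly linear in the operating parameters, and a
pure Gaussian expansion represents linear trends poorly near the domain
boundary (held-out R² collapses without the tail; with it, R² ≥ 0.999 on
the bioheat responses). With zero ridge the network interpolates training
data exactly; a near-singular kernel system triggers automatic ridge with
a warning. Accuracy metrics: per-sample relative error (min/max %), SSE,
SST, R² = 1 − SSE/SST and RMSE = √(SSE/k), reported for both the training
and the held-out split (the held-out numbers are the ones quoted).

## Interval propagation

The response interval of f over a box is [min f, max f]. The production
method runs bounded L-BFGS-B from the box centre, all 2^dim corners and 8
seeded random interior starts (the analytic RBF gradient is available);
the authoritative reference is a full tensor grid, default 9 points per
dimension. On the small 4-D boxes that arise here the two agree to well
under the reporting precision; tests require the local method to be at
least as extreme as the oracle. A degenerate (zero-radius) box
short-circuits to a point evaluation.

An operating condition is *unreliable* when the ST interval's upper bound
exceeds b = 45.5 °C, i.e. when its RPDI against b is below 1. Over the full
design domain the trained surrogate's ST interval reaches ≈68 °C — the
unoptimized condition is unreliable, which motivates the optimization.

## Interval optimization

Design variables are the midpoints of (t₁, d, h) with radii fixed at the
operating tolerances (2.5 °C, 0.15 mm, 0.8 mm); ω_c is an uncontrolled
uncertainty with fixed midpoint 40.5 % and radius 1.1 (the patient is not a
design variable). Midpoint bounds are the design domain shrunk by each
radius, so the whole interval stays inside the domain.

The RPDI pr(A ≤ B) = (Bᴿ − Aᴸ)/(2Aʷ + 2Bʷ) satisfies: it is unbounded;
A entirely below B forces pr ≥ 1; B entirely below A forces pr ≤ 0; and
pr(A ≤ B) + pr(B ≤ A) = 1. Against a crisp bound it degenerates to
(b − Aᴸ)/(2Aʷ). Both degenerate-degenerate comparisons resolve by the
limit convention (±∞, 0.5 at equality) rather than an error so optimizer
edge cases cannot abort a run. The constraint S(d^I) ≤ b becomes
(b − Sᴸ)/(2Sʷ) ≥ λ; at λ = 1 this is exactly Sᴿ ≤ b.

The interval objective is scalarized as the HPM interval **midpoint** by
default (lower/upper selectable) — the reported optimum depends on this
choice, hence it is prominent in the config.

Nested solve: a real-coded GA (population 40, 100 generations, binary
tournament, SBX crossover η = 15 at rate 0.9, polynomial mutation η = 20 at
rate 1/n, one elite, penalty 10⁴ per unit of reliability violation — so
infeasible-start populations still converge) searches the midpoint box;
every fitness evaluation builds the candidate's uncertainty box and
computes both response intervals on a 9-per-dimension tensor grid in one
batched surrogate call. The winner is re-verified against the same grid
oracle; a result is labelled feasible only if the re-checked RPDI meets λ
(within 10⁻⁹), otherwise the least-violating candidate is reported and
flagged. All randomness flows from one seed; identical seeds reproduce
identical midpoints bit for bit.

On toy problems with algebraic optima (linear 1-D: optimum midpoint 9 at
λ = 1, b = 10, radius 1; quadratic 1-D with an interior constraint
extremum: optimum 7; separable 2-D: optimum (7, 1.5)) the solver recovers
the optimum to <0.05 across seeds and matches exhaustive midpoint grid
search. On the bioheat surrogate the λ = 1.0 solution drives the ST upper
bound onto the allowable (the active-constraint signature) and the optimal
HPM is non-increasing in λ.

## Synthetic stand-ins: what they show and what they do not

The pseudo-simulators are closed-form (linear + mild interaction) surfaces
constrained only by (a) the sign structure established by single-factor
analysis — ST and HPM increase with t₁ and d and decrease with h; HPM
increases with ω_c — and (b) physiologic output bands (ST ∈ [38, 62] °C,
HPM ∈ [37, 45] °C). Coefficients are jittered ±8 % per seed and candidates
violating the invariants are rejected by finite-difference sign checks.
They exercise the sampling/surrogate/optimization plumbing cheaply; they do
not emulate transient dynamics, plateau behaviour, or grid effects, so
passing on the pseudo backend says nothing about PDE accuracy — that is
what the analytic-conduction, explicit-Euler and refinement checks are for.
Neither backend models moxa smoke, pharmacological or non-thermal effects,
and no claim about clinical efficacy follows from any test here.

## Problem sizes used in the shipped study

The shipped study (tests and the reproduction script) uses the coarse
preset, 50 training / 20 validation points, and the default GA; a full
pipeline run is ≈3 min on one CPU. The `fine` preset (~10× slower per
simulation) is available for spot checks; refinement moves the indicators
by <0.1 °C, which is why the coarse preset is the study default.

## Known limitations

- The absolute indicator scale depends on literature-chosen perfusion and
  emissivity values; only the qualitative structure (monotone trends, the
  domain straddling the allowable, the active constraint at λ = 1) is
  calibration-robust.
- The interval model is non-probabilistic by design; no distribution or
  percentile statements are possible.
- The moxa tip is a fixed-geometry disk; burning-front recession and smoke
  absorption are not modelled.
- Single-constraint formulation: only ST is constrained; adding constraints
  means adding RPDI terms, which the transform supports but the CLI does
  not expose.
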