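# Methods

This note documents the model implemented by `sectorsize`, the choices
made where the design was genuinely open, and what the synthetic tests do
and do not demonstrate.

## Model structure and assumptions

The proteome is partitioned into four sectors whose mass fractions sum to
one: ribosomal `φ_R`, metabolic `φ_P`, division `φ_X`, and an invariant
housekeeping sector `φ_Q` (so the dynamic budget is
`φ^max = 1 − φ_Q`).  Translation consumes a single coarse-grained
growth-limiting amino-acid pool with mass fraction `a`, replenished by
the metabolic sector.  Assumptions worth keeping in mind:

- **Constant protein density.**  Mass growth and volume growth are
  interchangeable (`κ = d ln M/dt = d ln V/dt`).
- **Two regulatory nonlinearities only.**  Nutritional efficiency is
  feedback-inhibited above `a_n` (`f(a) = 1/(1+(a/a_n)²)`), translational
  efficiency attenuated below `a_t` (`g(a) = (a/a_t)²/(1+(a/a_t)²)`).
  Hill coefficients are fixed at 2.
- **Allocation is an instantaneous function of `a`.**  The ribosomal
  allocation `f_R(a)` equals the steady-state flux-maximizing allocation;
  there is no explicit signalling delay.  `f_R*` is implemented in the
  algebraically reduced form
  `f_R* = (A φ_R^max + B φ_R^min)/(A+B)` with
  `A = v/(a_n²(1+u))`, `B = 1/(a_t²(1+v))`, `u = (a/a_n)²`,
  `v = (a/a_t)²`, obtained by cancelling the common factor of the
  derivative expressions symbolically; this evaluates to the exact limits
  `φ_R^min` at `a = 0` and `φ_R^max` as `a → ∞` without a guarded 0/0
  branch.
- **Threshold-accumulation division.**  A cell divides when the number of
  division proteins accumulated *since birth* reaches a fixed threshold;
  the normalized count obeys `dX̃/dt = k_P V − μ_X X̃` with
  `k_P = γ f_X (κ + μ_ns)`.  Division resets `X̃` to zero (the
  alternative — partitioning `X̃` between daughters — contradicts the
  since-birth counting) and jumps `V → r·V_d`; intensive variables are
  continuous across division because they are per-unit-mass quantities
  that partition proportionally.
- **Nutrients enter only through `κ_n⁰`.**  The mapping from external
  concentration to nutrient quality is not modelled; environments are
  piecewise-constant `κ_n⁰(t)` schedules.

## Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| `phi_R_min` | inactive ribosome fraction | – | 0.049 |
| `phi_R_max` | max flux allocation to ribosomes | – | 0.55 |
| `a_t` | translation attenuation threshold | – | 1e-4 |
| `a_n` | feedback inhibition threshold | – | 1e-3 |
| `kappa_t0` | translational efficiency constant | 1/h | 2.6 (4.8 for the size-law strain) |
| `mu_ns` | nonspecific degradation rate | 1/h | 0 (0.1 in stationary phase) |
| `mu_X` | division-protein degradation rate | 1/h | 2.5 (0.1 size-law strain) |
| `gamma_alpha` | co-regulated division production constant | µm⁻³ | 4.5 (3.6) |
| `gamma_beta` | basal division production constant | µm⁻³ | 1.1 (0.34) |

Units are fixed package-wide (hours, µm³); presets bundle the strain
parameter columns together with their poor/rich nutrient qualities
(`baseline` 4.8/10, `upshift` 4.8/160, `stationary` 0/160, `sizelaw`).

**Composite versus separated division parameters.**  Only the composites
`γα`, `γβ` are observable from size data, so they are primary.  When
`alpha`/`beta` are not supplied the package runs in *composite mode*: the
division sector's mass (at most `β`, a fraction of a percent of the
proteome) is neglected in the amino-acid balance, `φ^max = φ_R^max`, and
`φ_X` is carried γ-scaled (µm⁻³) as a diagnostic that feeds nothing back.
Supplying `alpha` and `beta` (with `γα/α = γβ/β`) switches on the full
mass balance; the conservation and degenerate-degradation tests run in
that mode.  All shipped presets use composite mode.

## Steady state, size law and calibration

At steady state `f_R = φ_R`, which reduces the fixed point to a
one-dimensional root-finding problem in `a` (bisected in log-space over
`[a_t/10³, a_n·10³]`; the residual is monotone).  `κ_n⁰ = 0` with
`μ_ns > 0` yields the stationary fixed point, where translation balances
turnover (`J_t = μ_ns`), division-protein production persists
(`k_P = γ f_X μ_ns`) and the division-protein *concentration* settles at
`k_P/μ_X` independent of size; with `μ_ns = 0` no fixed point exists and
a `NoSteadyStateError` is raised.

The generation cycle closes in closed form under symmetric division,
`X̃(birth) = 0` and `e^{κτ} = 2`:

    V₀ = (κ + μ_X) / [k_P (2 − 2^{−μ_X/κ})]

whose `μ_X → 0` limit is the adder expression `κ/k_P` and whose
`μ_X ≫ κ` limit gives the sizer set point `V_d = μ_X/k_P`.  This
re-derived closure is cross-validated against event-detected lineage
simulation (agreement ~1e-10 at steady state).

Two versions of `k_P(κ)` exist: the printed quadratic
`kP_steady` (which takes `g(a) ≈ 1`) used for fitting, and the exact
`kP_at_growth_rate` which inverts the monotone steady-state map
`κ(a)` (no `κ_n⁰` required) and is used internally by `solve()` and
`birth_size_full` so that formula and simulation agree to better
than 0.1%.

**Identifiability of the size-law fit.**  Inverting the size law gives
`1/V₀ = (γαΔφ + γβ) − (γα/κ_t⁰)κ`: exactly linear in `κ`.  Only the
intercept and slope are identifiable; `(γα, γβ, κ_t⁰)` cannot be
separated from `(κ, V₀)` data, and the degradation-corrected form has
the same ridge (`κ_t⁰` enters only through `γα/κ_t⁰`).  The fit
therefore treats `κ_t⁰` as a fixed, independently measured input and
estimates `(γα, γβ[, μ_X])`; `fit_kappa_t=True` opts into the full
3-parameter fit and flags the ridge in the results object.
Least squares is performed on `V₀` by default (log-space optional);
the Gauss–Newton covariance provides approximate standard errors.

`calibrate_from_observables` inverts the forward model: it root-finds
the `κ_n⁰` reproducing each observed growth rate, then solves the 2×2
linear system that the two observed birth volumes impose on
`(γα, γβ)`.  Round-trip recovery on model-generated observables is
exact to <0.1%.

## Numerical choices

- Stiff-aware adaptive integration (LSODA) at `rtol 1e-8`,
  `atol 1e-10`; the amino-acid pool equilibrates on ~1e-3 h timescales
  after shifts, far faster than proteome reallocation (~1/κ), which is
  the stiffness the solver absorbs.
- Environment switches restart the integrator at the segment boundary;
  the right-hand side is never discontinuous within a step.
- Division events are root-found on `X̃ − threshold` by the integrator's
  event machinery (|X̃ − θ| < 1e-8 at events, verified).
- Stochastic simulations exploit the model's shared-intensive structure:
  growth-rate offsets perturb only each cell's volume equation, so the
  intensive state `(a, φ_R, φ_X)` is integrated once per scenario and
  each cell integrates only `(V, X̃)` against it (RK45, `rtol 1e-9`).
  This is exact, not an approximation, given that noise enters volumes
  only.
- Division-ratio draws are truncated to (0.05, 0.95); thresholds are
  redrawn per generation only where threshold noise applies
  (stationary-exit protocol).  If a cell's effective growth rate goes
  negative during a deep downshift its volume shrinks; no floor is
  imposed, and division still requires `X̃ ≥ θ`.
- Generation averages use sliding bins (width 0.2 h, step 0.05 h) over
  division times; empty bins are reported as missing, never
  interpolated.
- The population growth rate is the discrete log-derivative of the cell
  count divided by ln 2 (doublings per hour, matching the printed
  estimator); a centered 0.25 h moving average smooths the
  discrete-count staircase.  Founder populations start spread uniformly
  over one steady-state cycle `(V₀*, 2V₀*)` with cycle-consistent `X̃`.

## Scenario defaults

- Stationary-exit ensembles draw initial volumes uniformly on
  `[0.3, 1.0] × V₀^max` (`V₀^max = 1/γβ`) and per-cell thresholds from
  `N(1, 0.05)` truncated positive; growth-rate noise is not applied
  there (it is a generational noise scaled by `⟨κ⟩`, which is zero in
  stationary phase).
- Growth-rate noise defaults `σ_κ = 0.15⟨κ⟩ + 0.02 /h`, giving the
  ~15% growth-rate CV typical of *E. coli*; both constants are
  configurable.
- Pulsed-feeding trains default to a 25% duty cycle (pulse duration
  0.25/feedrate) — the protocol fixes only the feed rate, not the duty
  cycle, so this is a package convention.
- Lag time `T_lag` is measured from feeding onset to the first division;
  recovery time applies a sustained-re-entry criterion (the series must
  *stay* within ±1% of the pre-shift level), which keeps the measure
  well defined for the non-monotonic interdivision-time recoveries seen
  after long pulses.  The 1% band is applied to the level itself.

## What the synthetic tests show — and do not

All validation data are generated by the model itself (fixture
generators, forward solves, simulations); no experimental measurements
ship with the package.  Passing tests therefore demonstrate internal
consistency — closed forms match event-detected simulation, fits recover
generating parameters, qualitative transition phenomenology (overshoots,
undershoots, phenotypic-memory saturation, population/single-cell
decoupling, lag-time monotonicities) emerges from the equations — but
not that the model describes any particular organism.  Calibration to
real (κ, V₀) tables is supported through the documented CSV interface
(`kappa_per_h,V0_um3[,weight]`).

Known limitations: no chromosome-replication coupling, no explicit
ppGpp/tRNA signalling, no nutrient-import kinetics or spatial structure,
no cell death; growth-rate noise is generational (no within-cycle
fluctuations); the composite mode neglects the (sub-percent) division
sector mass in the amino-acid balance.  One quantitative caveat from our
own simulations: at the stationary-exit defaults, first divisions occur
while the growth rate is still ramping, so the added-volume versus
initial-volume relation is an attenuated sizer (regression slope ≈ −0.3
rather than −1), and the resulting birth-size correlation is
correspondingly weaker than the ideal `μ_X ≫ κ` sizer limit, which the
test suite exercises separately at large `μ_X`.
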