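# Methods

## Model and assumptions

`larvenet` models a single leaf-chewing larva on a glucosinolate-defended
host plant over its development window [0, b] days. Development is taken
to be a genetic program unfolding in time, which motivates
*non-autonomous* linear dynamics: each rate is an explicit function of
time rather than of larval mass or state. Consequences and caveats:

- **Herbivory** H' = θt gives quadratic cumulative consumption H = θt²/2.
  θ is a single constant across instars; in reality per-instar feeding
  rates differ (the final instar dominates consumption), so the single
  parabola is a deliberate smoothing. H and G are truncated to zero for
  t > b — feeding stops when development ends — while the toxin and
  energy states are pure functions of t ≥ 0 and are only *interpreted*
  on [0, min(T, b)].
- **GLS ingestion** is strictly proportional to herbivory (G = αt²/2):
  the leaf is treated as chemically homogeneous, so every mg of tissue
  carries the same toxin load. Spatially heterogeneous defence
  distribution is out of scope.
- **Free gut GLS** F' = αt − ηF is solved exactly but assumed to remain
  negligible (quasi-steady state): hydrolysis and sequestration outpace
  ingestion, consistent with feces assays that detect no free GLS. The
  package *checks* this rather than assuming it (below).
- **ITC exposure** I' = βt − γI lumps all hydrolysis products into one
  toxic species formed at rate βt (instantaneous degradation of ingested
  GLS makes the forcing linear in t) and cleared first-order at rate γ
  (excretion plus glutathione conjugation). No partitioning into
  nitriles/epithionitriles or sequestered fractions.
- **Net energy** EN' = κt − μI − δt² is the optimal-foraging ledger:
  benefit proportional to feeding (κt), toxin cost proportional to gut
  ITC concentration (μI), foraging cost proportional to the herbivory
  curve (δt²). Fitness is identified with net energy; when EN returns to
  zero the larva cannot afford further feeding. Death is taken as implied
  when that happens well before b — no post-stopping starvation lag is
  modelled.

Units: time in days and herbivory in mg (anchored by the packaged
consumption table); GLS/ITC amounts, concentrations and energy are in
arbitrary but internally consistent units, since no physical units exist
for them in the source data.

## Parameters and defaults

| parameter | meaning | unit | default |
|---|---|---|---|
| θ | herbivory growth constant | mg·day⁻² | 0.3 |
| α | GLS ingestion growth constant | toxin-mass·day⁻² | 0.4 |
| η | free-GLS degradation rate | day⁻¹ | 40 |
| β | ITC formation constant | conc·day⁻² | 0.2 |
| γ | ITC clearance rate | day⁻¹ | 0.8 |
| κ | energy-benefit constant | energy·day⁻² | 0.3 |
| μ | toxin-cost constant | energy·conc⁻¹·day⁻¹ | 0.1 |
| δ | foraging-cost constant | energy·day⁻³ | 0.03 |
| EN0 | innate energy at hatching | energy | 0.2 |
| b | development time | day | 14.58 |

The defaults are the package's reference scenario: a generalist-type
larva with appreciable toxin exposure. b = 14.58 d is the summed
per-instar duration of the packaged codling-moth table. η has no
published value; 40 day⁻¹ makes α/η = 0.01, deep inside the regime the
quasi-steady-state argument requires, and η feeds nothing downstream (the
ITC equation already assumes immediate degradation), so its exact value
only matters to the diagnostic.

Validation: θ, α, β, κ, μ, δ, EN0 ≥ 0; η, γ, b > 0 (γ appears in
denominators). EN0 < μβ/γ³ raises a warning, not an error: the energy
solution would dip below zero immediately after t = 0, which is
biologically impossible, but the functions remain evaluable and sweeps
may legitimately cross that threshold.

## Stopping time

EN is unimodal whenever any cost is present: its rate κt − μI − δt² has
a strictly decreasing derivative κ − (μβ/γ)(1 − e^(−γt)) − 2δt, so the
rate changes sign at most once and EN rises then falls. The zero
crossing T is therefore unique, and a coarse bracket cannot miss it.

- **Numeric route**: 10⁴-point grid on (0, 10b] to bracket the sign
  change, then Brent's method to |EN(T)| ≤ 1e−9·max(1, EN0) (in practice
  ~1e−15). The 10b horizon is a pragmatic cutoff: a stopping time beyond
  ten development times is biologically indistinguishable from survival.
  If no crossing occurs the result carries T = None, and the survival
  field is None (undecidable) when the horizon did not reach b.
- **Degenerate case** EN0 = 0: the leading small-t behaviour
  EN ≈ κt²/2 decides analytically whether energy rises (κ > 0) or is
  negative immediately (κ = 0 with any cost); the latter is reported as
  a flagged T = 0 outcome, not an exception. The analytic branch is used
  because evaluating the closed form at tiny t is pure cancellation
  noise.
- **Analytic route**: dropping e^(−γT) and the offset EN0 − μβ/γ³ and
  dividing by T gives the quadratic (δ/3)T² + ((μβ/γ − κ)/2)T − μβ/γ² = 0.
  Its constant term is ≤ 0, so with δ > 0 and μβ > 0 exactly one positive
  root exists whatever the sign of κ − μβ/γ. The stable branch of the
  quadratic formula is used (no subtraction of like-signed terms), a
  result is accepted only after verifying it annihilates the truncated
  energy polynomial to 1e−9 (relative), and degenerate sub-cases (δ = 0,
  μ = 0) reduce to their linear/factored roots — returning None when the
  truncated energy never crosses zero. A closed-form radical printed for
  this root elsewhere did not withstand re-derivation from the quadratic;
  this implementation solves the quadratic itself and relies on the
  residual check.
- **Survival rule**: dies_early iff finite T < b. T = b counts as
  survival (feeding stops exactly at development's end), and T = None is
  survival.

## Quasi-steady-state diagnostic

F = (α/η²)(ηt − 1 + e^(−ηt)) never departs from the quasi-steady value
αt/η by more than α/η². The qualitative claim "free GLS ≈ 0" is
quantified as: the peak free pool on [0, b] must stay below 1% of the
total GLS ingested over development, G(b) = αb²/2 — a detection-limit
reading of the feces assays. The threshold is monotone in η, so speeding
up degradation can only help. With the defaults the margin is wide
(peak F is 0.34% of G(b)).

## Fitting

- **θ**: H = θt²/2 is linear in θ, so least squares through the origin
  has the closed form θ̂ = 2ΣHᵢtᵢ²/Σtᵢ⁴. Data are anchored at instar
  *end* times (running sum of durations) because the table records
  cumulative consumption per completed instar; midpoint anchoring would
  be a defensible alternative but is not the default. The fitting
  criterion itself (ordinary least squares on cumulative values) is a
  package choice — the source data are means without an error model.
  κ is *not* estimable from consumption data: the benefit term has the
  same t² shape as herbivory, so κ is only identifiable given energy
  measurements. On the packaged table θ̂ = 0.3097 mg/day² with SSE
  dominated by the final instar, which a single growth constant cannot
  track exactly.
- **(β, γ)**: nonlinear least squares on the ITC curve, multi-started
  over γ ∈ {0.1, 0.5, 1, 2, 5} day⁻¹ with β initialised from the
  late-time slope times γ (the curve's asymptotic slope is β/γ); the
  best converged start by SSE wins. All-zero data short-circuit to
  β̂ = 0 with γ flagged unidentifiable; total non-convergence returns a
  failure result carrying per-start diagnostics.

## Synthetic data

Generators emulate the two observable tables: per-instar cumulative
consumption (quadratic mean curve at running-sum times) and ITC time
courses (saturating-slope mean curve). Noise is multiplicative
lognormal, value·exp(σZ) with Z ~ N(0,1) — the natural choice for
strictly positive measurements; the factor has median 1 and mean
exp(σ²/2), and no bias correction is applied. Default σ = 0.05 (a 5%
coefficient of variation, typical of replicated feeding-assay means);
σ = 0 reproduces the model exactly. Because a noised running total can
momentarily decrease, consumption draws are repaired by cumulative
maximum (plus a 1e−9 relative bump on exact ties) to preserve the
cumulative-measurement semantics. All generators are pure functions of
(parameters, seed).

What the generators do *not* emulate: between-individual variance,
instar-transition stochasticity, measurement-time jitter, or any
systematic departure from the model's own curve shapes. Passing
recovery tests therefore demonstrates internal consistency of the
estimators under the assumed error model, not robustness to model
misspecification in field data.

## Numerical choices

- Closed forms use the shared ramp-relaxation kernel
  (r/c²)(ct − 1 + e^(−ct)); for ct < 1e−4 a fourth-order series
  replaces it to avoid catastrophic cancellation, making the c → 0 limit
  (rt²/2) continuous to machine precision.
- The cross-check integrator is LSODA at rtol 1e−8 / atol 1e−10: the
  free-GLS equation is stiff once η ≫ 1/b (η = 100 gives ηb ~ 10³), and
  a stiffness-switching method keeps the global error on all five states
  below ~3e−7 against the closed forms — comfortable headroom under the
  1e−6 equivalence bound the tests enforce. Grids may not extend past
  10b (runaway-horizon guard).
- Regular grids clamp their final point to the requested stop so that
  floating-point accumulation cannot push it past b and spuriously
  trigger the piecewise truncation of H and G.
- Test problem sizes: 100-draw ensembles for the closed-form/ODE and
  root-finding cross-checks (401-point grids; dense oracle at 1e−4-day
  steps), 20 noise replicates for recovery studies. These sizes give
  sub-minute suites while exercising the full parameter ranges.

## Known limitations

- No larval mass/size growth model: net energy is the fitness proxy, and
  linking it to development curves is future work.
- No indirect plant defence (natural-enemy recruitment), no insecticide
  scenarios, no instar-dependent θ, no post-stopping time-lag mortality
  model.
- The sharp T < b death rule ignores any tolerance band around b; a
  larva stopping marginally before b is classified as dying early.
- Energy and concentration scales are arbitrary; only ratios of the
  cost/benefit constants are meaningful across parameter sets.
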