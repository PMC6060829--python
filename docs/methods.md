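# Methods

## The problem

Given angles θ₁…θₙ on the circle (radians, reduced to [0, 2π)), test the
null hypothesis that they are drawn from the uniform distribution with
density 1/2π. Alternatives of scientific interest fall into two families:
unimodal concentration around one direction (e.g. homeward orientation)
and multimodal concentration (e.g. crepuscular activity with peaks at dawn
and dusk, axial orientation along a magnetic field line). No single test
is best against both, which is why the package carries seven and a power
engine to compare them.

## Test statistics and p-values

All statistics reject in the upper tail. `n` is the sample size,
`r = |Σ e^{iθᵢ}|/n` the mean resultant length, `u_(i) = θ_(i)/2π` the
sorted angles rescaled to the unit interval.

| test | statistic | default p-value |
|---|---|---|
| Rayleigh | `r` (significance via `R = n·r`) | Wilkie approximation `exp(√(1+4n+4(n²−R²)) − (1+2n))` |
| V | `V = r·cos(θ̄ − μ₀)` | upper normal tail of `u = V√(2n)` with the O(1/n) and O(1/n²) Edgeworth terms `φ(u)[(3u−u³)/16n + (15u+305u³−125u⁵+9u⁷)/4608n²]` |
| Kuiper | `Vₙ = max(i/n − u_(i)) + max(u_(i) − (i−1)/n)` | asymptotic series on the Stephens-modified `Vₙ(√n + 0.155 + 0.24/√n)` |
| Watson | `U² = Σ(u_(i) − ū − (2i−1)/2n + ½)² + 1/12n` | alternating series on the Stephens modification `(U² − 0.1/n + 0.1/n²)(1 + 0.8/n)` |
| Rao spacing | `U = ½ Σ|Tᵢ − 2π/n|` over arc gaps incl. wrap-around | Monte-Carlo |
| Hermans–Rasson | `T = n⁻¹ ΣᵢΣⱼ [‖θᵢ−θⱼ|−π| − π/2 − 2.895(|sin(θᵢ−θⱼ)| − 2/π)]` | Monte-Carlo |
| Bogdan (adaptive smooth) | `N_{k*}`, `N_k = Σ_{j≤k}(c_j²+s_j²)`, `c_j = √(2/n)Σcos jθᵢ`, `k* = argmax_k N_k − 2k·log n`, k ≤ 10 | Monte-Carlo, selection re-run per null draw |

Choices worth recording:

- **V-test tail correction.** The plain normal tail is anticonservative at
  n ≈ 25 (level ≈ 0.053); with the correction terms the measured level is
  0.050 at n ∈ {10, 25, 100} (100k-replicate check). The analytic levels of
  all four closed-form tests sit within ±0.002 of nominal over that range.
- **Hermans–Rasson kernel.** The pairwise kernel above (tuning constant
  2.895, which weights the |sin| term so power extends to multimodal
  alternatives) is the form the test's proponents distribute; because the
  null is simulated, the test is exactly valid whatever the constant, and
  the constant only shifts power.
- **Bogdan penalty.** Each Fourier harmonic contributes a cosine/sine pair,
  i.e. two parameters, so the Schwarz penalty is 2k·log n. `max_dim = 10`
  harmonics are considered by default. The selection rule runs inside every
  calibration draw; skipping that (calibrating `N_k` at fixed k) makes the
  test anticonservative.
- **Monte-Carlo p-values** use `p = (1 + #{null ≥ observed})/(reps + 1)`,
  which cannot return 0 and gives an exactly valid test; with R null draws
  the achievable level at α is `floor(α(R+1))/(R+1)`, which is why tables
  use R = 9,999 by default (exact 0.05) and R = 99,999 in the headline
  type-I run. A null table depends only on (test, n) and is reused across
  an entire sweep — this is what makes 10,000-replicate grids desk-scale.
- **Ties are legal** everywhere; zero spacings are valid Rao inputs.
  α is always a parameter, never hard-coded.

## Distributions

- **von Mises(μ, κ)**: density `exp(κ cos(θ−μ))/2πI₀(κ)`; sampled with the
  Best–Fisher rejection algorithm (numpy's generator). κ = 0 is uniform.
- **wrapped Cauchy(μ, ρ)**: density `(1−ρ²)/2π(1+ρ²−2ρcos(θ−μ))`; sampled
  by drawing a linear Cauchy with scale γ = −ln ρ and wrapping. ρ = 0 is
  uniform.
- **wrapped skew-normal(ε, ω, α)**: the linear skew-normal wrapped mod 2π;
  sampled via scipy's skew-normal; density summed over wraps |k| ≤
  8·max(1, ω/2π) (wrap truncation checked by quadrature: densities
  integrate to 1 within 1e−6). Dispersion grows with ω, so power falls as
  ω rises. The simulation convention is ε = 0, α = 30 (right skew).
- **von Mises mixtures**: categorical component choice, then a component
  draw. `mode_mixture(f, placement, κ)` builds the standard equal-weight
  layouts: symmetric = f modes at 360°·k/f; asymmetric = modes 0° and 90°
  for f = 2, and 180°/(f−1) increments (0°…180°) for f ≥ 3. The f = 2
  asymmetric case is a deliberate special case: the general spacing rule
  would reproduce the symmetric layout there, which is not what breaking
  the symmetry means.

Samplers are validated against quadrature CDFs (99% Kolmogorov band at
10,000 draws) and are exactly reproducible given a generator or seed.

## Power engine

One cell = (generator, n, test, α): draw `reps` samples of size n, apply
the test, report the rejection proportion p̂ and SE `√(p̂(1−p̂)/reps)`.
Design points:

- **Paired comparisons.** All tests in a cell see the *same* simulated
  samples, so between-test power differences have far smaller variance
  than independent runs; `rejection_matrix` exposes the indicators so the
  paired SE of a difference can be computed.
- **Seeding.** Per-cell streams derive from
  `SeedSequence(master, spawn_key=(1, sweep_index, n_index))` and null
  tables from `spawn_key=(0, k)`; cells are independent, individually
  re-runnable, and a one-cell scenario reproduces
  `estimate_rejection_rate` exactly.
- **Scenario catalogue** (`reference_scenario`): the study conditions are
  the defaults — 10,000 replicates per cell (100,000 for the type-I
  scenario), α = 0.05, n = 25 for the multimodal sweeps, sample sizes
  {10, 15, 20, 25, 30, 40, 80, 100} for type-I, {15, 25, 40, 100} for the
  unimodal and mode-separation sweeps; κ from 0 to 6 in 0.1 steps; mode
  separation Δ from 0° to 180°; mixture weight 0.05–0.5 in 0.05 steps at
  κ ∈ {2, 3}; second-mode κ swept with the first fixed at 3. Grids the
  study does not print were fixed once as conventions: κ ∈ 0–4 step 0.5
  and ω ∈ 0.5–5 step 0.5 for the unimodal sweeps, ρ ∈ 0–0.9 step 0.1 for
  the wrapped Cauchy, Δ step 10°. `reps` is overridable everywhere; the
  tests and the acceptance script run reduced sizes (1,000–10,000
  replicates, stated in each test) with tolerances widened by the matching
  binomial allowance.

## What the synthetic data do and do not show

The generators emulate exactly the idealised laws of the simulation study:
i.i.d. draws, known families, no measurement rounding, no serial
dependence, no grouping. Real orientation data are often aggregated to
5–10° bins, serially correlated within individuals, or mixtures across
individuals; none of that is modelled, so a test passing here guarantees
calibration and relative power under the idealised conditions only.
Grouped-data corrections are explicitly out of scope.

## Confidence arcs for the mean direction

`mean_direction_ci` is a percentile bootstrap (default 9,999 resamples):
resampled mean directions are centred on the sample mean direction via
signed circular differences in (−π, π], and symmetric percentiles of the
centred deviations form the arc. This avoids any distributional
assumption, consistent with the omnibus spirit; an analytic
dispersion-based interval could be added but is not. Coverage is checked
by simulation (von Mises, κ = 8, n = 100: nominal 95% within the binomial
3σ band over 300 datasets). The mean direction is declared undefined when
r < 1e−12 (numerically exact symmetric grids); the arc is reported in the
sample's input unit.

## Numerical notes

- Angle reduction is half-open [0, 2π); degrees are converted at the
  boundary and echoed on output, printed with 12 significant digits so
  file round trips are lossless to ~1e−12.
- The Kuiper/Watson tail series are truncated at 100 terms and clipped to
  [0, 1]; deep in the null body (modified statistic below 0.2 / 0.005
  respectively) the alternating series cancels catastrophically and the
  p-value is set to 1, which is correct to <1e−3 there.
- The Hermans–Rasson double sum is O(n²) and evaluated in memory-bounded
  chunks; a 99,999-draw null table at n = 25 takes ~2 s on one core.
- Von Mises density uses the exponentially scaled Bessel I₀ for stability
  at large κ.

## Known limitations and honest discrepancies

- With the 2k·log n Bogdan penalty, the adaptive smooth test is *more*
  powerful than Hermans–Rasson in the symmetric bimodal sweep (κ = 3,
  n = 25: ≈0.83 vs ≈0.77 at 10k replicates), and Hermans–Rasson sits
  ≈12 points below Rayleigh-after-doubling there — a larger gap than the
  qualitative "almost as good" the power study reports for the whole
  curve. The robustness claims that drive the recommendations (HR has the
  best minimum power over the mode-separation sweep; HR ≥ Rao throughout;
  raw Rayleigh blind to symmetric bimodality) all reproduce.
- Under the wrapped skew-normal at n = 100, Kuiper exceeds Rayleigh by up
  to ≈3.2 points (ω = 4), slightly above the 1–2 point ceiling the study
  describes; the wrapped-skew-normal dispersion convention (linear-scale
  ω) is the most literal reading but not the only one.
- Published Rao critical-value tables are not implemented; Rao p-values
  are always Monte-Carlo.
- Axial-data conventions beyond the f-fold transform, circular-circular
  association, two-sample tests and parameter estimation are out of scope.
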