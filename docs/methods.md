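# Methods

## Model

Tree cover is a vector `x(t)` of per-size-class cover fractions on the unit
simplex (`x_i ∈ [0,1]`, `Σ x_i ≤ 1`), updated yearly. Two nonnegative
Lefkovitch matrices describe survival and class progression: `A_nf` for a
fire-free year and `A_f` for a fire year; entry `(i, j)` is the proportion of
class-`j` cover moving to class `i`, and a column-sum deficit is mortality.
After the survival/transition update, new seedlings are recruited into the
smallest class.

The fire indicator `F(t)` is Bernoulli with probability `p(C)`, a
non-increasing piecewise-linear function of the effective cover `C`:
`p = p_max` at or below `θ1`, `p = p_min` at or above `θ2`, linear in
between. This encodes the fire–grass–tree feedback: less tree cover means
more grass fuel and a higher fire probability, so fire begets fire and its
absence begets absence. Grass biomass is only implicit; the two thresholds
stand for the fuel loads at which fire becomes near-certain and
near-impossible, and default to `p_max = 1`, `p_min = 0`.

Three modelling decisions that the equations do not force:

- **Recruitment form.** Recruitment is space-limited:
  `b = a (1 − Σ_j (A x)_j) e1`, i.e. a fraction `a` of the free space left
  after the update enters class 1. This is the simplest form that (i) recruits
  only into the smallest class, (ii) respects the stated update order
  (survival first, recruitment second), (iii) keeps the state on the simplex
  for *any* valid stage matrices, and (iv) yields the affine closed form
  `x* = (I − Ã)⁻¹ a e1` with `Ã = (I − a e1 1')A`. A constant-recruitment
  variant (`b = a e1`, `space_limited: false` in the config) is provided; it
  can leave the simplex for aggressive configurations, which raises an error
  rather than silently clipping (violations beyond 1e-9 are errors; smaller
  ones are treated as float noise and clipped).
- **Fire-draw timing.** `F(t)` is drawn from `p` evaluated at the
  *pre-update* state `x(t)`: the fuel that carries a fire exists before that
  year's mortality happens. Year `t`'s cover is therefore attributed to the
  dynamic indicated by `F(t)` in all statistics.
- **Effective cover.** `C` is the cover summed over the classes named in the
  fire model's `cover_mask` (all classes when unset). In the three-class
  example the mask is {2, 3}: seedlings under 1 m carry neither fuel
  suppression nor canopy, so both the feedback *and the vegetation cover
  itself* are canopy quantities. All cover statistics (histograms, means,
  bimodality index, chain cover distribution) use this same cover, which
  coincides with the total for a single class.

## Steady states and stability

Forcing a constant dynamic makes the map affine, `x → Ã x + a e1`, with the
unique fixed point `x* = (I − Ã)⁻¹ a e1` when the spectral radius of `Ã` is
below 1 (`steady_state` raises otherwise). The operative sufficient condition
for stability of the *switched* system is `‖Ã‖₁ < 1` for both dynamics
(maximum column sum): the 1-norm is submultiplicative, so every mixed product
of the two maps then contracts. The scaled maximum-element norm
`n·max|ã_ij|`, which upper-bounds the induced 1-norm, is reported alongside.
With space-limited recruitment the column sums of `Ã` are `(1−a)` times those
of `A`, so any valid stage pair with `a > 0` is stable.

`invert_fire_thresholds` solves the reverse problem used by the fire-regime
sensitivity analysis: given target fire probabilities `p_nf` at the
undisturbed and `p_f` at the disturbed steady state (in the `p_max=1,
p_min=0` regime), the linear branch through the two points gives
`θ2 − θ1 = (C*_nf − C*_f)/(p_f − p_nf)` and `θ2 = C*_nf + p_nf (θ2 − θ1)`;
targets whose thresholds escape [0, 1] are infeasible (the triangular domain
with a cut corner seen in the fire-regime grid).

## Ulam discretization

The cover domain is partitioned into hypercube cells of width δ (1/δ must be
an integer; cells are half-open `[l, l+δ)`, the last cell closed). A cell is
accepted when its *center* satisfies `Σ center ≤ 1` — the center test, chosen
for consistency with evaluating the per-state fire probability at centers.
For one class the affine maps are monotone and the conditional transition
matrices are computed *exactly* from interval overlaps; for `n > 1` they are
estimated by mapping a regular sub-grid of 5 points per axis per cell
(configurable) and counting destination cells. Points whose destination cell
was rejected by the center test (possible next to the simplex face) are
assigned to the nearest accepted cell. By total probability the chain is the
state-dependent mixture `T[i,·] = (1−p_i) T_nf[i,·] + p_i T_f[i,·]`.

The stationary vector solves `wT = w` by power iteration from the uniform
vector (L1 tolerance 1e-13, capped at 10⁶ iterations) with a direct linear
solve — one equation replaced by the normalisation — as cross-check and
fallback; the result is accepted only if `‖wT − w‖₁ < 1e-10`. Irreducibility
and aperiodicity are checked via strongly connected components and the gcd of
BFS cycle lengths. When several closed classes exist the stationary vector is
not unique: a warning is issued and the uniform-start limit returned.
Feedback configurations can genuinely produce reducible chains — e.g. when
the disturbed steady-state cover lies below `θ1`, the `p = 1` region is
absorbing — and the warning is the intended signal.

## Statistics

- **Permanence ratios**: fractions of post-burn-in years under each dynamic.
  The burn-in defaults to 100 years, discarding the spin-up influenced by the
  initial state.
- **Fire chain**: the empirical 2×2 transition matrix of `F(t)`; rows never
  visited are NaN and flagged, not imputed. Fire clustering shows as
  `P(1→1)` exceeding the marginal fire frequency.
- **Bimodality index** `B = |μ* − μ|`, where μ is the mean cover and μ* the
  mean cover associated with the *more frequent* dynamic, estimated from a
  histogram with the same bins (default width 0.1, half-open, last bin
  closed, centers at `l + Δ/2`). Both means use the binned estimator
  `Σ c_k f_k / Σ f_k`: mixing a raw mean with a binned one would carry a
  systematic half-bin offset (a point mass at cover 1.0 would score
  B = 0.05 from binning alone — half the classification threshold). The
  unbinned mean is reported as `mu_raw`. `B ≥ 0.1` classifies the
  distribution as bimodal; the verdict is a pure threshold function.
  Dominance ties are broken toward no-fire and flagged.
- **Chain mode**: on a discretized chain, μ bins the state covers with
  weights `w_i` and μ* with weights `w_i p_i` (fire dominant) or
  `w_i (1−p_i)` — the stationary analogue of labelling years by `F(t)`.
  Dominance is `Σ w_i p_i` vs 1/2.
- **Pooled mode**: the same estimator over sites sampled at one instant,
  emulating a spatial survey.

## Reference configurations

All named configurations are package choices: the field parameters they stand
in for are not derivable from first principles, so they were fixed once by
the mechanism analysis below and are not data estimates.

- `scalar_reference_config` — retentions 0.9 (no fire) / 0.4 (fire),
  `a = 0.1`, thresholds (0.2, 0.8). Steady states 0.526 and 0.156. Because
  the disturbed cover lies below `θ1`, the fire regime is absorbing: the
  chain concentrates at 0.156 and the simulation follows. This makes it a
  sharp oracle for chain-vs-simulation agreement, degenerate limits and
  permanence consistency.
- `scalar_fast_growth_config` — retentions 0.9 / 0.05, `a = 0.45`. A
  package analysis of the switching mechanism shows slow demographies cannot
  be bimodal for *any* threshold setting: with `a = 0.1` the no-fire map
  contracts at only 0.19/yr, so the climb back to high cover spends ~10
  years exposed at fire-prone intermediate covers while the fire-driven
  descent takes ~2, and the high mode never accumulates mass (sensitivity
  scans: max B ≈ 0.05). Bimodality requires both dynamics to contract
  quickly toward well-separated steady states; this configuration contracts
  at ≈ 0.5/yr in both regimes (steady covers 0.891 / 0.463).
- `scalar_bimodal_config` — the fast-growth demography with thresholds
  inverted so `p = 0.05` at the undisturbed and `p = 0.9` at the disturbed
  steady state: both regimes are sticky, transitions are quick, and B ≈ 0.14
  by trajectory and chain alike.
- `three_class_reference_config` — synthetic stand-in matrices (labelled as
  such) with fast canopy turnover and fire top-kill, mask {2, 3}, `a = 0.45`,
  thresholds inverted at (0.05, 0.95) on the canopy steady states (0.56 /
  0.10). Gives sharp savanna↔forest transitions, strong fire clustering and
  a bimodal canopy distribution (B ≈ 0.15 across seeds).

## Experiment designs

- **Sensitivity grids.** The demographic sweep varies the two retentions over
  the triangle `alpha_f ≤ alpha_nf` (fire cannot improve survival), holding
  recruitment and fire parameters at the base configuration; the fire-regime
  sweep varies the target probabilities over `p_f > p_nf`, realised through
  threshold inversion, skipping infeasible points. Each feasible point runs a
  fresh 5000-year simulation (burn-in 100) with a counter-based child seed,
  so grids are reproducible point-by-point. Axis choice for the demographic
  sweep: the no-fire retention controls how fast cover grows without fire,
  the fire retention the resistance to fire — the two parameters that set the
  attraction toward the undisturbed and disturbed states.
- **Spatial ensembles.** Independent scalar sites draw parameters uniformly
  from per-parameter bands and are simulated with per-site child seeds; the
  pool of (cover, fire status) at one sample time (default t = 300, burn-in
  100) is summarised like a field snapshot. `bimodal_site_design` brackets
  the bimodal example (every site individually bimodal);
  `two_band_site_design` draws the fire retention from two disjoint bands —
  very vulnerable (0.05–0.2) and very resistant (0.85–0.95) trees on a
  high-retention demography — so each site is unimodal (low- or high-cover)
  but the pool is bimodal. Sites split evenly and deterministically between
  the two bands (alternating site index). The band edges are package
  choices emulating the contrast between fire-adapted savanna species and
  fire-sensitive forest species; they are not field estimates.
- **Problem sizes.** The test suite and acceptance script use: 10⁶-year
  simulations for the chain oracle, 10⁵ years for permanence/clustering,
  5000-year runs per sensitivity grid point (step 0.05 → 20 values per
  axis), ensembles of 1000 sites over 350 years sampled at t = 300, and 100
  random configurations for convergence/invariance sweeps. These sizes give
  sampling noise well inside the decision margins of every check (e.g. TV
  noise ~10⁻³ against a 0.02 bound).

## What the synthetic setups do and do not show

The generator-side configurations reproduce the mechanism — switching-induced
bimodality without bistability, fire clustering, sharp non-catastrophic
transitions, pooled-sampling bimodality — under demographically plausible but
invented parameters. Passing tests demonstrate the mechanism's internal
consistency (simulation vs. discretized chain vs. closed forms), not that any
real savanna has these parameter values. Real tree-cover data add spatial
contagion of fire, rainfall variability, herbivory, measurement error and
correlated site parameters, none of which are modelled: the ensemble sites
are strictly independent and the landscape is space-implicit.

## Known limitations

- The Ulam chain's cost grows as `(1/δ)^n`; for three classes δ = 0.1
  (≈ 200 states) is practical, δ = 0.01 is not. The n > 1 transitions are
  sampled, not exact.
- The bimodality index detects separation between the dynamic-conditional
  means, not multimodality per se; distributions with more than two modes or
  heavily overlapping modes are outside its design.
- With `p_max < 1` or `p_min > 0` the threshold-inversion routine refuses to
  run (the closed form assumes the 0–1 regime).
- Stage matrices are annual and time-homogeneous; no seasonality, ageing
  within classes, or density dependence beyond the shared space constraint.
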