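# Methods

## Angle conventions

All user-facing angles are topographic compass degrees on [0, 360): 0° =
magnetic North, increasing clockwise. Internally the compass angle is used
directly as the polar angle (cosine = northward, sine = eastward
component); every statistic in the package is equivariant under a global
rotation, so the convention only matters at the I/O boundary, where
`compass_to_rad` / `rad_to_compass` are the single conversion point.
Angles read from CSV are normalized into [0, 360) immediately.

## Second-order circular analysis

Worms on one plate interact and cannot be treated as independent samples.
The orientation analysis therefore proceeds in two stages:

1. **First order** — each plate's worm headings are summed as unit vectors;
   the resultant gives the plate mean direction µ_j and mean resultant
   length r_j ∈ [0, 1]. When r_j = 0 (perfect cancellation) the mean
   direction is undefined and flagged as such; downstream consumers must
   handle the flag (such plates cannot contribute a direction to stage 2
   and are dropped from it with a warning — under any realistic dispersion
   this is a measure-zero event).
2. **Second order** — the plate mean directions, one **unit** vector per
   plate, form the sample actually tested. The Rayleigh statistic is
   Z = n r² with n the number of kept plates, and the p-value uses the
   series approximation

   p = exp(−Z) · [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288 n²)],

   clipped into [0, 1]. The approximation error is a few 1e−4 at n ≈ 25 and
   shrinks with n; a Monte-Carlo check at n = 8 (20,000 uniform samples)
   confirms a 5% ± 1% rejection rate at α = 0.05. Plate r_j values do not
   enter the Rayleigh test (which requires unit observations); they are
   reported per plate and the second-order r feeds the bootstrap below.

## Bootstrap comparison of directedness

To ask whether one group is more *directed* than another, the second-order
angles of the reference group are resampled with replacement (n angles per
draw, 100,000 draws by default), r is recomputed for each draw, and the
sorted r values at the 1-based ranks ⌈N(1−c)/2⌉ and ⌊N(1+c)/2⌋ (2,500 and
97,500 for N = 100,000, c = 0.95) give the confidence limits. A comparison
group whose observed r lies below the interval is significantly more
directed at p < 0.05; containment means no significant difference. The
resampled objects are orientation angles (each contributing a unit vector),
not length-weighted plate vectors. The generator is a seeded
`numpy.random.Generator`; the same seed reproduces the interval bit for
bit. Resampling is chunked (20,000 draws at a time) to bound memory.

## Kernel density estimates

Raw headings are displayed via a von Mises kernel density: the equal-weight
mixture of von Mises densities centered at the data angles with
concentration κ equal to the `bandwidth` parameter (default 40, the
convention of circular density estimators with von Mises kernels — larger
is narrower; κ = 40 ≈ 9° kernel SD). The normalizer uses the exponentially
scaled Bessel function `i0e`, so κ up to several hundred is computed
without overflow. Values are per radian on a 512-point grid by default; for
a periodic smooth function the trapezoidal (equivalently, mean × 2π)
integral is spectrally accurate, so the unit-integral invariant holds to
1e−6 without renormalization, and a single-point sample reproduces the
closed-form von Mises density exactly.

## Two-target assay

Each plate yields PI = (T − C)/(T + C) ∈ [−1, 1], undefined when no worm
reached either circle (such plates are dropped with a warning). Groups are
compared with the two-sided Mann–Whitney U test, implemented in-package:
the exact null distribution of U (classic lattice-path recurrence) is used
when min(n₁, n₂) ≤ 8 and the pooled values are tie-free — exactness where
it is cheap — and otherwise the normal approximation with tie correction
and continuity correction, which is reproducible and matches the standard
reference implementation to 1e−6. No multiple-testing adjustment is
applied; the diacetyl-vs-control comparison reuses the same code path as
magnet-vs-control.

## Plate-inclusion filters

Defaults: ≥ 30 worms scored (inclusive; derived from the headings table,
never a separate column, to prevent inconsistency), humidity < 50% (strict,
evaluated at assay start), max(start, end temperature) ≤ 25 °C (inclusive —
the threshold is read as applying to the warmest reading), |ΔT| < 2 °C
(strict), duration 55–65 min (inclusive). Inclusivity follows the literal
wording of the protocol each rule encodes. Filtering is idempotent; the
exclusion log lists every excluded plate with all violated rules, so the
log is the exact complement of the kept set. A chi-square goodness-of-fit
test against equal group allocation (α = 0.05) reports whether filtering
unbalanced the group sizes; it is advisory, never a gate.

## Synthetic data

The generators encode the minimal model honoring the two statistical
commitments of the assay design: plate-level non-independence and a
directional preference at a fixed compass angle.

* **Orientation assay** — plate mean directions µ_j ~ von Mises(µ_pop,
  κ_between), worm headings θ_ij ~ von Mises(µ_j, κ_within); κ = 0 draws
  exactly uniform angles rather than relying on the sampler's limit.
  Defaults: µ_pop = 305° (the preferred angle to the field lines reported
  for starved worms), κ_between = 0 (null), κ_within = 1 (plate-level r
  around 0.45, comparable to real plate dispersions), ~75 worms per plate
  (truncated Poisson, ≥ 1; assays release 50–100 worms). Worm–worm coupling
  is modeled only through the shared plate mean, not pairwise interaction.
  Metadata for filter-passing plates is drawn uniformly inside the pass
  region (humidity 30–49%, start temperature 20–23.5 °C, |ΔT| < 1.4 °C,
  duration 56–64 min); a configurable fraction of plates instead violates
  exactly one randomly chosen rule (the temperature drift violation drifts
  downward so it cannot simultaneously trip the maximum-temperature rule).
* **Two-target assay** — total scored worms ~ truncated Poisson (default
  mean 60), split T ~ BetaBinomial(N, p_target, ρ) with intra-plate
  correlation ρ (ρ = 0 reduces to binomial; ρ > 0 reproduces the
  plate-to-plate overdispersion of preference indices).
* **Mechanistic walk** (optional) — a correlated random walk from the plate
  center: wrapped-normal turning noise, heading blended toward a target
  direction with weight b ∈ [0, 1], exit angle recorded at the rim.
  b = 0 gives statistically uniform exit angles, b = 1 ballistic motion.
  Walks not reaching the rim within a step cap are dropped with a warning.

What the generators deliberately do not emulate: real worm locomotion
(speed, reversals, pirouettes), paralytic kinetics, worm–worm contact, or
any physical field effect. Passing tests therefore demonstrate that the
*analysis* is calibrated and powerful under the hierarchical model, not
that any particular biological effect exists.

## Calibration and power checks (sizes used)

* Null calibration: 1,000 replicates of 26 plates × 100 worms (uniform
  plate means) give a second-order Rayleigh rejection rate of 5% ± 1.5% at
  α = 0.05; a further 300-replicate Kolmogorov–Smirnov check confirms the
  null p-values are uniform.
* Direction recovery: 500 replicates of 24 plates × 80 worms at
  κ_between = 2 around 305°. The circular mean of the recovered
  second-order directions lies within 10° of 305° (unbiasedness) and the
  Rayleigh test rejects uniformity in ≥ 95% of replicates (power). Note a
  single replicate's direction estimate has a circular SE of
  1/√(n·ρ̄·κ) ≈ 9.9° at these settings (ρ̄ = I₁(2)/I₀(2) ≈ 0.70), so
  per-replicate ±10° containment is capped near 69% by the design itself —
  unbiasedness, not per-replicate containment, is the meaningful recovery
  property at this sample size.
* Bootstrap: for samples of n ≤ 4 the Monte-Carlo CI endpoints match the
  exhaustive enumeration of all nⁿ resamples within ±0.02; the percentile
  CI brackets its own point estimate in ≥ 93% of null replicates (measured
  ≈ 98% — the percentile construction rarely misses its own center).
* Walk uniformity: 100 replicates × 300 bias-free walkers; pooled Rayleigh
  test retains uniformity and per-replicate rejections stay inside the
  binomial(100, 0.05) 99.9% envelope.

## Numerical choices and degenerate inputs

* r is clipped to [0, 1] against rounding overshoot; r ≤ 1e−12 flags the
  mean direction undefined (reported as null, never as 0°).
* Empty samples, invalid weights (negative, wrong length, zero-sum),
  κ ≤ 0 bandwidths, grids < 16 points, bootstrap samples of < 2 angles,
  negative counts and unknown condition labels all raise descriptive
  errors; CSV validation errors name the offending row numbers.
* The pipeline derives one child seed per condition from the master seed
  via `SeedSequence.spawn` in sorted-condition order, so reports are
  byte-identical given identical inputs and seed, and per-condition results
  do not shift when unrelated conditions change.
* JSON reports serialize floats at full precision (`repr` round-trip), are
  schema-versioned, and embed the software version and seeds.

## Known limitations

* The Rayleigh series p-value is an approximation; at n < 10 its tail error
  is visible (the Monte-Carlo calibration bounds it at ±1% for n = 8).
  Exact Rayleigh quantiles are not implemented.
* Second-order alternatives that are directed but axially symmetric
  (bimodal) are invisible to the Rayleigh test; axial doubling, Watson,
  Kuiper and Moore tests are out of scope.
* The bootstrap compares directedness only through r; it does not test
  direction agreement, and confidence cones for µ are not provided.
* The balance check assumes equal intended allocation across conditions.
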