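# Methods

## Model

Excess lifetime beyond age 110 is modelled as `X ~ Exponential(λ)` — the
mortality-plateau hypothesis, under which the one-year survival
probability `e^{−λ}` does not depend on age, sex, nationality or any
other covariate once age 110 is reached. The model-checking alternative
is the Generalized Pareto family with location 0 (scale σ, shape ξ),
which nests the exponential at ξ = 0 with λ = 1/σ.

Registries include a death only if it falls in a country window
`[b, e]`. With `t` the decimal year the person turned 110 and
`x = age − 110` at death, the per-record likelihood is the conditional
density of `x` given observability:

- C1 (`t ≤ b`): divide by `F(e−t) − F(b−t)`;
- C2 (`t > b`): divide by `F(e−t)`.

Both reduce to `f(x)/[F(hi) − F(lo)]` with `lo = max(b−t, 0)`,
`hi = e−t`; an unbounded window end gives `F(hi) = 1`. The Bayesian
analysis multiplies this truncated likelihood by the scale-invariant
prior `π(λ) ∝ 1/λ`; the truncation factors enter the posterior as
divisors, exactly as in the frequentist likelihood. For untruncated data
the posterior is `Gamma(n, Σx)`, which the test suite uses as a conjugate
oracle for the sampler.

## Conventions and parameters

- **Decimal years.** Dates map to `year + (day_of_year − 0.5)/year_length`
  (events at mid-day); excess age is `(death − birth in days)/365.2425 −
  110` and `t = death_time − x`. The registry metadata do not fix a
  day-count convention; 365.2425 (the mean Gregorian year) is this
  package's documented choice.
- **Year-only deaths** are imputed to July 1 (`year + 0.5`), the registry
  convention for records lacking an exact date; January 1 and
  December 31 variants support sensitivity checks.
- **Boundary `t = b`** is classified C1.
- **Window violations are hard errors**, not silent drops: inclusion is
  guaranteed by the registry's design, so a violation means corrupted
  input.
- **Regions** for the stratified tests are North America (CA, US),
  Northern Europe (BE, DE, DK, EW, FI, NO, SE), Southern Europe (AT, ES,
  FR) and Japan.
- **ΔBIC convention**: `df·ln(n) − Λ`, positive favouring the null
  (single-rate) model, with `n` the records entering both fits.
- **GP vs exponential LRT** uses the ordinary chi-square(1) reference
  (the shape is unrestricted in sign, so the null is interior).
- **Optimisation**: λ by bounded 1-D search on `[10⁻⁶, 50]` per year
  (absolute tolerance 10⁻¹⁰); GP by Nelder–Mead in `(ln σ, ξ)` started at
  the exponential solution and polished with BFGS.
- **Bootstrap**: parametric, holding every record's `(t, window)` fixed
  and redrawing `x` from the fitted law conditioned on observability —
  the same conditioning the likelihood uses. Whether attainment times
  should also be regenerated is genuinely open; conditioning on them
  matches the likelihood's fixed-`t` treatment and keeps the resampling
  design identical to the estimand. Percentile intervals; seeded;
  replicates whose refit fails are dropped (error above 5%).

## Posterior sampling

Random-walk Metropolis–Hastings on `θ = ln λ` with the Jacobian
correction, which keeps λ positive without boundary rejections. Defaults:
110 000 iterations, 10 000 burn-in, no thinning — effective sample sizes
of several thousand on registry-sized data. The proposal scale, if not
supplied, is adapted in batches of 200 during burn-in toward acceptance
in [0.2, 0.5] and frozen afterwards, so the retained chain is a valid MH
chain. Acceptance outside [0.05, 0.95] or ESS < 100 triggers warnings.
For n < 2 the normalizing integral on `[10⁻⁶, 50]` is checked finite by
quadrature before sampling (the 1/λ prior can be improper on degenerate
inputs). Posterior density plots use a Gaussian kernel with Silverman
bandwidth.

## From band counts to attainment cohorts

Projection software reports `P`, the count aged 110–114 at 5-year grid
points. Assuming attainments uniform over the preceding 5 years and
exponential survival, the expected band occupancy is
`N(1 − e^{−5λ})/(5λ)`, so the attainment cohort is `N = M(λ)·P` with
`M(λ) = 5λ/(1 − e^{−5λ})` (M → 1 as λ → 0, ≈ 3.76 at λ = 0.733). Counts
at grid year `y` are read as attainments during `(y−5, y]`, so the grid
2025–2080 covers attainment cohorts 2020–2080 — leaving those who turn
110 in 2080 time to die before 2100; lifetimes are not right-truncated at
2100, since the fitted model makes survival far past age 130 negligible.
`N` is kept real-valued throughout; the maximum-order-statistic formulas
accept non-integer `N` as their continuous extension, avoiding rounding
bias.

## MRAD composition

Each of `T = 10⁵` iterations draws λ uniformly from the posterior draws
and a trajectory uniformly from the set — independently, because the two
posteriors come from disjoint data — computes `N = M(λ)·ΣP`, and draws
the maximum of `N` exponential lifetimes by inverting
`(1 − e^{−λx})^N` (computed as `−ln(−expm1(ln u / N))/λ` for accuracy at
large `N`). Iterations with `N = 0` are tallied as "no supercentenarian"
rather than resampled, so exceedance probabilities, computed against all
`T` iterations, stay unconditional.

## Synthetic data

The generator defines the study conditions for every test:

- **Records.** Per country, attainments follow a homogeneous Poisson
  process over `[b − lead, e]` (default lead 20 y); lifetimes are
  exponential at the configured true rate (default 0.733/yr); a record is
  retained iff the death lands in `[b, e]`. Thirteen countries with
  windows spanning 10–35 years and intensities giving one dominant
  country, several mid-sized and a long tail; female share 0.92. The
  stationary process keeps the inclusion probability analytic (a
  quadrature oracle in the tests); real registries have growing
  attainment schedules, for which a linear-ramp intensity option exists.
  With `target_retained` set, attainers are drawn until the requested
  retained count is reached — valid because attainment times conditional
  on the Poisson count are iid uniform, so retained records remain iid
  from the truncated law.
- **Trajectories.** `P_k(y_j) = base · growth^j · ε_{k,j}` on the
  2025–2080 grid with log-normal `ε` (sd `dispersion`, 70% of the
  variance a trajectory-level shared factor so paths are coherently high
  or low). Defaults: base 280 at 2025, growth 1.5 per 5 years (roughly
  doubling per decade), dispersion 0.35 — a 95% band about twice the
  median by late century, and a 2020–2080 attainment cohort of order
  10⁵, the scale at which record-breaking ages become near-certain.

What passing tests on these stand-ins show: the likelihood, sampler,
cohort conversion and Monte Carlo composition are each correct against
independent oracles (closed forms, conjugacy, quadrature, brute-force
simulation), and the composed pipeline reproduces the semi-analytic
mixture `1 − E[(1 − e^{−λ(a−110)})^N]`. What they do not show: that the
exponential model, the registry's verification standards, or any
particular projection fan describe the real world — those claims need
the registration-gated registry data and real projection exports, which
this package consumes but does not ship.

## Numerical notes and limitations

- Exponential window probabilities use `log1p/expm1` forms; survival
  functions handle unbounded window ends exactly.
- A GP fit with ξ < 0 assigns −∞ log-likelihood to out-of-support points
  rather than erroring, so optimisers can retreat; a window configuration
  with zero observable probability is an error.
- The descriptive one-year survival statistic is a raw proportion with no
  truncation adjustment — it mirrors registry summary plots and is biased
  at ages where windows bind.
- The empirical trajectory set weights every trajectory equally; no
  parametric smoothing of projection uncertainty is attempted.
- Currently living supercentenarians are excluded by construction (the
  registry holds only deaths); forecasts therefore apply to deaths from
  2020 on, and only to the covered countries.
- Problem sizes in the test suite (replicate counts, chain lengths,
  Monte Carlo iteration counts) are chosen so each check resolves its
  stated tolerance with seeded reproducibility.
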