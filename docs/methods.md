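# Methods

## Model

The linear-logistic dose–response model is

    y(x) = a + b·x − c / (1 + d·e^(−f·x)),

a line of slope `b > 0` minus a logistic drop of amplitude `c ≥ 0`
centred at dose `m = ln(d)/f` with rate `f > 0`.  The sign convention
(`b, d, f > 0`, `c ≥ 0`) is fixed rather than free: it is what makes the
curve rise–dip–rise and what makes the stationary-dose formulas
well-defined.  `c = 0` is the admissible degenerate pure-line case.

Zeroing the derivative `y′ = b − c·d·f·e^(−fx)/(1 + d·e^(−fx))²` and
substituting `u = e^(−fx)` gives `b·d²u² + (2bd − cdf)u + b = 0`, with
discriminant proportional to `Δ = c·f(c·f − 4b)`:

* `Δ > 0` — two stationary doses, `Rmax = −ln(u₊)/f < Rmin = −ln(u₋)/f`
  with `u± = (cf − 2b ± √Δ)/(2bd)`.  Since `u₊u₋ = 1/d²`, always
  `Rmax + Rmin = 2·ln(d)/f` exactly.
* `Δ = 0` — a single flat point at `ln(d)/f`.  Numerically, the
  boundary is declared at `|cf − 4b| ≤ 1e−10·max(cf, 4b)`; without this
  band, floating-point noise at the boundary would produce spurious
  complex roots.
* `Δ < 0` (or `c = 0`) — strictly increasing curve; no stationary doses
  exist and the package says so (`monotone` regime) rather than
  reporting meaningless doses.

The radical form `√(cf(cf − 4b))` follows directly from the quadratic;
a test verifies the closed form against bracketing/bisection of the
derivative on 1000 random parameter sets.

All curve evaluations route the logistic term through
`c·expit(f·x − ln d)`, which cannot overflow however large `|f·x|`
gets — relevant because percent-of-requirement dose axes make
`f·x ≈ 100` routine.

## Fitting

`fit_linlog` is multi-start nonlinear least squares.  Internally doses
and responses are affinely standardised to `[0, 1]` (back-transformed on
exit, so reported coefficients are in the caller's units and the fit is
invariant to affine dose rescaling); the optimiser works on
`(a, ln b, ln c, m, ln f)` with the sigmoid parameterised by its midpoint
`m`, which enforces the sign constraints without penalties and
conditions the 5-parameter problem.  The start grid is deterministic:
the line is anchored by OLS on the upper third of the dose range (where
the curve has re-joined its linear trend), the dip amplitude at 1–3×
the largest downward residual from that line, the midpoint at the
interior dose quantiles {0.25, 0.4, 0.5, 0.6, 0.75}, and the rate at
{2, 5, 10} per unit of scaled dose range — 45 starts, best local
optimum kept.  The model surface is multi-modal; nothing short of
multi-start is reliable, and a deterministic grid keeps every run
reproducible.  Trust-region reflective least squares with tolerances
1e−13 recovers noiseless truths to ~1e−6 relative.

Replicates are fitted as individual observations by default (this
preserves the error structure the bootstrap resamples); a
`collapse_replicates` flag fits dose-level means instead, since
published analyses sometimes fit means only — both modes are exposed
because which one a given published analysis used is usually unstated.

Segmented (linear-plateau) regression is a continuous two-phase model:
for fixed breakpoint the two coefficients are closed-form OLS, so the
breakpoint is profiled over 1001 equally spaced candidates plus the
observed dose levels (vectorised), then polished by bounded scalar
minimisation in the bracketing cells.  The fitted breakpoint cannot
leave the observed dose range.  Orientation (rise-then-plateau vs
plateau-then-rise) is auto-detected by RSS unless forced.  Quadratic-
plateau (quadratic to its vertex, then flat) and a four-parameter
logistic use the same standardise/log-parameterise machinery; the plain
quadratic is exact OLS.

Model selection uses AICc with `k` = mean-model parameters + 1 for the
residual variance; "best goodness of fit" needs a concrete criterion
and AICc is deterministic and small-sample aware (titration tables are
small).  RSS is floored at 1e−300 inside the log so numerically exact
fits rank properly; ties below ΔAICc = 1e−6 break toward fewer
parameters, then alphabetically.  On designs too small for a candidate
(e.g. five coefficients on four level means) the candidate is skipped
and recorded, not raised.  AICc is `+inf` when `n ≤ k + 2`, which
removes over-parameterised candidates on tiny designs.

`nearest_treatment` maps an estimated dose onto the actual treatment
grid; exact midpoints resolve to the larger dose (the conservative
choice given that doses at and above the dip are the ones carrying
functional benefits), documented and trivially changeable.

## Uncertainty

`bootstrap_ci` is a case bootstrap stratified by dose level: within each
level, observations are resampled with replacement, preserving the
design's level structure — appropriate because titration designs have
few levels and possibly level-dependent variance, which a residual
bootstrap would homogenise.  Intervals are percentile intervals
(default B = 1000, α = 0.10); BCa is deliberately not implemented.
Replicate streams are spawned from one root `SeedSequence`, so results
are bit-reproducible and independent of execution order.  Replicate
refits are warm-started at the full-data estimate (a single start);
rerunning the full 45-start grid per replicate changes nothing
detectable at these noise levels and costs 40× the time.  Replicates
whose refit loses the dip (monotone/degenerate regime) have no
stationary doses; they are counted in `failed_replicates`, and a result
with > 50% failures is flagged unreliable rather than reported as if
sound.

`compare_rmin_to_breakpoint` operationalises "the companion response
plateaus at Rmin": fit the linear-logistic model to the primary
(growth) table, segmented regression to the companion, and classify by
which stationary dose is nearer to the breakpoint in absolute dose
units (ties go to Rmin), with an optional nearest-treatment mapping.
No formal equality test is attempted — the underlying claim in the
literature is made visually, and a distance-based classification is the
smallest honest formalisation.  A monotone primary yields an explicit
"pattern not detectable" report.

## Synthetic studies

The generator emulates the titration designs this analysis targets:
4–8 dose levels over ranges like 77–127 (AA:Lys ratio, %) or
0.95–1.45 (% of diet), few replicates per level, additive homoscedastic
Gaussian noise specified either in response units or as a fraction of
the noiseless response range.  Defaults: 6 levels uniform on 77–127,
8 replicates, noise 3% of range — the densest design layout among the
studies this model family is applied to.  The default truth places
Rmax = 97 and Rmin = 117 with line slope 2 and baseline 200 response
units, built by `params_from_geometry`, which inverts the stationary-
dose formulas so fixtures can pin their truth exactly where a test
needs it.

Companion responses are generated as a continuous linear-plateau (or
logistic rise) whose breakpoint (or midpoint) sits at a chosen anchor —
typically the primary's true Rmin — mimicking paired growth/physiology
panels.  Count-like companions (survival, litter size) are generated as
Gaussian around the mean curve; binomial noise is out of scope.  What
passing tests therefore show: the estimation machinery recovers known
truths under the stated designs and Gaussian noise.  What they do not
show: robustness to heteroscedastic or skewed biological error,
animal-level covariates (genetics, age, dietary fiber), or
time-dependent attenuation of the dip.

`recovery_study` runs seeded simulation grids and reports bias, RMSE
and median absolute error of the estimated Rmax, Rmin and breakpoint
per design cell, with fit failures reported as a rate, never raised.

## Numerical and design choices

* Discriminant boundary tolerance 1e−10 (relative); degenerate regime
  is returned, never an exception, at `cf = 4b`.
* Problem sizes in the shipped validation harness: 1000 random
  parameter sets for the closed-form/numeric agreement check; 200
  simulated studies for recovery; 200 studies × 200 bootstrap
  replicates at α = 0.10 for coverage calibration; 100 low-noise pairs
  per anchor for coincidence classification.  These sizes give
  Monte-Carlo error comfortably below the tolerances being checked
  while keeping the whole harness at a few minutes on one CPU.
* All CLI randomness flows from one `--seed`; JSON reports store floats
  at full precision (repr round-trip), the TSV summaries display 6
  significant digits.
* Input is plain CSV/TSV with a header (delimiter sniffed); rows with
  missing dose or response are dropped with a logged count.

## Known limitations

* Homoscedastic least squares only; no weighted, mixed-effects or
  Bayesian variants.
* Percentile bootstrap can undercover slightly at very small replicate
  counts; BCa would improve this and is future work.
* The coincidence classification is descriptive, not a hypothesis test.
* `d = exp(f·m)` overflows for dose axes whose offset is enormous
  relative to their range (offset/range ≳ 100); the fitter raises a
  clear error rather than returning a non-finite coefficient.
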