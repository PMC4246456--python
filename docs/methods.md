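# Methods

## Data model and observation process

The unit of analysis is a duration-event table: one observed duration per
subject (months from treatment start) and an event flag (recovered vs
right-censored). The simulated observation process mirrors a two-year
multi-centre follow-up design:

- **administrative censoring** at a single horizon (default 24 months):
  a latent duration beyond the horizon is recorded at the horizon with
  the event flag off. Staggered entry and loss to follow-up are not
  modelled — every censored record sits exactly at the horizon, the
  simplest mechanism consistent with a fixed follow-up window, and the
  `Cohort` validator enforces it whenever a `StudyDesign` is attached.
- **recording floor** (default 0.5 months): recoveries within days of
  treatment start are conventionally recorded at half a month. The
  generator left-rounds latent durations up to the floor (still events).
  No other discretisation is applied.

Latent durations come from one of four laws with fixed parameterisations
(months throughout): exponential S(t) = e^(−t/θ) with θ a scale (mean);
Weibull S(t) = e^(−(t/α)^β); log-normal S(t) = 1 − Φ((ln t − μ)/σ) with
natural logs; power law S(t) = (t/t_min)^(−k) truncated at t_min (the
untruncated survival diverges as t → 0, so a lower truncation point is
required and must sit at or above the floor). Sampling uses the
corresponding scipy distributions (`expon`, `weibull_min`, `lognorm`,
`pareto`).

θ and the log-normal parameters deserve a note, because fitted values
are often printed without stating conventions. θ is treated as a scale:
θ ≈ 6 months is consistent with a long-tailed cohort, whereas a rate
of 6/month would not be. μ, σ are in natural-log units: e^1.15 ≈ 3.2
months matches a 3-month median, whereas base-10 would imply a
14-month median.

### The deterministic reference cohort

`make_reference_fixture()` rebuilds a 90-subject cohort from published
interval summaries of a depression cohort: cumulative recovery 26% by
1 month, 63% by 3, 85% by 12, 91% by 24. Percentages convert to
cumulative event counts by round-half-up (23, 57, 77, 82 of 90; any
rounding convention lands within ±1 subject, but one must be fixed); the
remaining 8 subjects are censored at the horizon. Events are placed at
the right endpoint of their reporting interval. Endpoint placement is
deliberate: the summaries are "recovered **by** t" statements, and it is
the only deterministic placement that also reproduces the published
3-month median — spreading events across the 1–3 month interval would
drag the S ≤ 0.5 crossing to ≈ 2.3 months. The resulting KM fractions
are 25.6/63.3/85.6/91.1%, each within rounding of the printed values.

What passing tests on this fixture do show: the estimator, summaries and
diagnostics reproduce the published figures from the published interval
data. What they do not show: anything about within-interval timing in the
real cohort, which the summaries do not determine.

## Kaplan–Meier estimation

`kaplan_meier` delegates the product-limit computation to lifelines and
re-exposes it as an explicit step function over the distinct event times
with risk/event/censoring counts. Conventions (the field's standard
ones): censorings tied with an event time are in that time's risk set
(censoring resolves after events); S is right-continuous, so "fraction
recovered by t" = 1 − S(t) includes events at exactly t; the median is
the smallest event time with S ≤ 0.5 (a 1e-12 tolerance absorbs float
noise in the product; an all-censored cohort is rejected, and a curve
that never reaches 0.5 raises a dedicated error). The test suite checks
the implementation against an independent brute-force oracle that
enumerates risk sets directly.

Greenwood variances and confidence bands are out of scope — the
analyses this package reproduces report none.

## Censored maximum likelihood

All three families share the right-censored likelihood
ℓ = Σ_events ln f(tᵢ) + Σ_censored ln S(tᵢ), evaluated on the individual
records (not on KM points; least squares on KM points is reserved for the
log-log trend, matching how the two procedures are used in practice).
The exponential MLE is closed form, θ̂ = Σ tᵢ / d (total observed
exposure over event count). Weibull and log-normal are maximised
numerically via the lifelines fitters; whatever lifelines reports, the
stored log-likelihood is recomputed from the formula above at the fitted
parameters, so AIC comparisons are internally consistent.
Non-convergence is returned as a fit with `converged=False`, a
diagnostic message, and ℓ = −∞ rather than an exception. Model
comparison ranks by AIC = 2k − 2ℓ with ties broken toward fewer
parameters, and refuses to compare fits whose event/censoring counts
differ (a proxy for "same cohort").

Test oracles: numeric maximisation for the exponential closed form, a
refined dense grid search for a two-point Weibull fit, log-moment closed
forms (divide-by-n sd) for uncensored log-normal data, and the algebraic
identity that the Weibull likelihood at β = 1 equals the exponential
likelihood at θ = α on any cohort.

## Probability paper and the linearity score

Each family's paper transform maps its exact survival function to a
straight line: exponential (t, −ln S); Weibull (ln t, ln(−ln S));
log-normal (ln t, Φ⁻¹(1 − S)); power law (log₁₀ t, log₁₀ S). The points
are the KM step values at event times — no Blom/median-rank plotting
positions, since the input is already a censoring-adjusted estimate
rather than raw order statistics. Points with S ∈ {0, 1} have no finite
transform and are dropped (counted); at least three usable points are
required. Straightness is the squared Pearson correlation of the
transformed points, unweighted — a simple quantitative proxy for the
classical by-eye judgement, chosen as a design decision, with
degenerate exactly-collinear (horizontal) point sets scored 1. r² is
invariant under affine rescaling of either axis, so the score does not
depend on time units.

## Power-law trend and the hazard ∝ 1/t model

The trend is ordinary least squares of log₁₀ S on log₁₀ t over the KM
event-time points (S = 0 dropped, unweighted). Base 10 is the plotting
convention for double-logarithmic axes; the slope is base-invariant and
the intercept is stored as log₁₀ S(1 month), with A = 10^intercept and
k = −slope. The companion model dN/dt = −kN/t (recovery hazard k/t,
decreasing in episode duration) has solution N(t) = A·t^(−k);
`verify_ode_solution` confirms this by central finite differences
(default step 1e-4, residual < 1e-6 over 1–24 months). The survival is
clipped at 1 because the prefactor exceeds 1 below t = A^(1/k); t_min
defaults to the 0.5-month floor and evaluation below it is a domain
error. Clauset-style maximum-likelihood tail fitting and formal
log-normal-vs-power-law likelihood-ratio tests are out of scope: within
a two-year window the two laws are not statistically separable and the
package does not pretend otherwise.

## Generative mechanisms

`multiplicative_process` multiplies an initial value by n i.i.d. factors
with ln F ~ Normal(m, s). The factor law is fixed to log-normal
deliberately: the product is then *exactly* log-normal at every step
count, so the central-limit claim behind "multiplicative ⇒ log-normal"
is testable without asymptotics (other positive factor laws would only
approach log-normality). `reflected_process` applies
x ← max(barrier, x·F) per step — hard reflection at a bounded minimum;
with negative drift (m < 0) the chain keeps returning to the barrier and
the stationary distribution acquires a power-law upper tail. Non-negative
drift with a barrier is allowed but warns, since no stationary tail is
then guaranteed. The resampling variant of the barrier is out of scope.

`tail_linearity` scores the upper tail (default: top decile, where the
log-normal/power-law disagreement lives) by OLS straightness of the
log-log empirical complementary CDF. One caution, visible in the tests:
over a single decade a log-normal tail is itself quite straight
(r² ≈ 0.98 at the default configuration), so the diagnostic is used as a
*contrast* — the reflected chain scores higher than its barrier-free
twin, and a Lilliefors test rejects log-normality of the reflected
samples (1% level) while not rejecting the barrier-free ones. The
default reflected configuration (500 steps, m = −0.1, s = 0.5,
barrier 1, 10⁴ chains) was calibrated once in pilot runs to reach a
clearly stationary tail; it is a simulation-design choice, not an
empirical claim about depression.

## Simulation experiments: sizes and tolerances

- Parameter recovery at the published fitted values (θ = 5.99;
  α = 5.61, β = 0.85; μ = 1.15, σ = 1.14): cohorts of n = 100 000
  censored at 24 months, 4 replicates per family in the tests; the
  acceptance band is |mean − truth| < 3 Monte-Carlo standard errors
  estimated from the replicates. A smaller 40 × n = 500 version runs per
  family in the unit suite.
- These recovery and model-selection experiments use a negligible
  recording floor (10⁻⁹ months) so the data-generating process is
  exactly the model being fitted: the 0.5-month floor is a recording
  convention of real studies, and clamping ~5% of log-normal mass to
  0.5 months would bias μ̂ by ≈ +0.03 — real, but a property of the
  recording rule rather than of the estimator under test. Study-condition
  defaults elsewhere keep the 0.5-month floor.
- Model selection: 100 replicates of n = 500 log-normal cohorts; both
  the AIC ranking and the probability-paper ranking must put log-normal
  first in ≥ 95 replicates (observed: 100/100 at the frozen seed).
- Distributional correctness of the generators: Kolmogorov–Smirnov test
  of 10⁵ latent draws against the specified CDF, p > 10⁻³.
- Numerical tolerances: exact identities at 1e-9…1e-12; closed-form vs
  numeric optima at 1e-4…1e-6 (optimizer precision); simulation checks
  at 3–4 standard errors.

## Known limitations

- Administrative censoring only; no dropout process, no covariates
  (treatment dose, comorbidity), no interval censoring.
- No standard errors or confidence intervals for fitted parameters.
- The reference fixture pins down only what the published interval
  summaries determine; within-interval event times are a convention.
- The fitted log-normal's implied recovery fractions do not exactly
  match the published KM percentages (e.g. S(1) ≈ 0.84 vs a printed 74%
  remaining); the discrepancy is in the source analysis itself and is
  reproduced, not corrected.
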