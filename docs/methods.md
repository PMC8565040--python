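# Methods

## The estimation problem

Population surveys underestimate alcohol consumption: the total implied by
self-reports typically accounts for only a fraction (the survey *coverage*)
of the per-capita consumption (APC) recoverable from administrative data on
production, sales and trade. The model implemented here triangulates the two
sources. For every year *y*, sex *g* and age group *a* it estimates

* the prevalence of current drinkers `p_{y,g,a}`,
* the distribution of average daily consumption among drinkers, assumed
  Gamma with mean `mu_{y,g,a}` (grams of ethanol/day) and shape
  `alpha_{y,g,a}`,
* per-survey coverage, decomposed as `c_{s,g,a} = c'_s * c''_{g,a}`: an
  overall factor for survey *s* times sex-age deviations shared by all
  surveys and constant over time.

## Likelihood

**Consumption.** Each survey cell is summarised by interval tuples
`{lc, uc, pc, ne}`: the share `pc` of drinkers whose reported daily intake
falls in `[lc, uc]` grams/day, and an effective sample size `ne`. Because a
Gamma variable scaled by `c` is again Gamma with rate divided by `c`,
reported (under-reported) consumption is `Gamma(alpha, beta / c_{s,g,a})`
with `beta = alpha / mu`. A tuple contributes
`ne * pc * log P[lc <= X <= uc]` — a multinomial-style weighted
log-likelihood in which `ne` acts as a sample size. Open-ended top intervals
use the survival function; exact reports (weekly drink counts divided by
seven) enter through the density. This mixes probability and density scales
in one objective, as the tuple definition implies; an optional
`point_halfwidth` setting instead widens a point report into a narrow
interval (half a drink per week, ~0.86 g/day) for users who prefer a pure
probability likelihood.

**Prevalence.** Survey estimates `pp` are normal around the model
prevalence with their design-based standard errors `pse`.

**APC constraint.** For each year the population total
`sum_{g,a} mu * pop * p` is normal around `(1 - w) * apc_y` with sd
`apcse_y`, where `w` is the wastage fraction (share of recorded alcohol
never drunk; default 0.2, with `w = 0` as a sensitivity setting). APC
series in litres of pure ethanol per capita per year are converted to
grams/day with ethanol density 0.78924 kg/L and 365.25 days/year.

**Smooth surfaces.** `log mu` and `logit p` are tensor-product spline
surfaces over year and age, one coefficient tensor per sex. The
one-dimensional bases are low-rank thin-plate regression splines (radial
basis `|x - k|^3` on the distinct axis values, constrained orthogonal to the
`{1, x}` polynomial space and eigen-truncated), with the polynomial space
prepended, so constants and linear trends are exactly representable and
dimension 2 reduces to a linear trend. Axes are internally rescaled to
[0, 1]; defaults are dimension 4 per axis at full scale and (3, 2) on the
scaled test grid (5 years x 3 age groups), the largest dimensions the short
axes support without near-collinearity. Age groups enter through
representative midpoints.

## Priors

* **Shape.** `alpha ~ N(r_g, rs_g)` with `r = 1.171^-2 ~ 0.73`,
  `rs = 0.028` for males and `r = 1.258^-2 ~ 0.63`, `rs = 0.036` for
  females — an informative prior expressing the near-constant sd/mean ratio
  of consumption distributions observed across populations. The shape is
  parameterised on the log scale, which truncates the prior to positive
  values (a Gamma shape must be positive).
* **Soft cap.** An informative one-sided penalty on the 95th percentile of
  each cell's distribution: zero while `q95 <= 150` g/day, then a half-normal
  penalty on the excess with scale 5 g/day. This keeps the estimated mass
  above physiologically implausible intakes negligible without a hard
  truncation that would distort the likelihood surface.
* **Coverage.** `logit c'_s ~ N(0, 1.5)` — broad on (0, 1). The deviations
  are parameterised as `log c''` with a sum-to-zero constraint (geometric
  mean exactly one — the identifiability normalisation: without it,
  rescaling all `c'` by a constant and `c''` by its inverse would leave the
  likelihood unchanged) and prior `N(0, 0.025)` per cell, so deviations
  beyond ~5% are two-sd events. Deviations are constant over time.
* **Spline coefficients.** Independent `N(0, 3)` on each coefficient — a
  weakly-informative choice on the log/logit scales. A hierarchical scale
  with a half-normal hyperprior was considered and rejected: it adds a
  funnel geometry that costs far more sampling effort than the smoothing it
  buys on these grid sizes, where the basis dimension already controls
  smoothness.

## Computation

The joint posterior is sampled with a No-U-Turn Sampler written against the
exact gradient of the log posterior. All gradient terms are analytic except
the derivative of the regularised incomplete gamma function with respect to
its shape argument, which is evaluated by a central difference with relative
step 6e-6 (absolute accuracy ~1e-11, far below sampler tolerances).
Per-chain preparation finds the posterior mode with L-BFGS and builds a
dense Laplace covariance from a finite-difference Hessian there; that
covariance seeds the sampler's metric and disperses the chain starting
points. During warmup, dual averaging adapts the step size towards a 0.8
acceptance statistic and expanding windows re-estimate the (dense) metric
from warmup draws, shrunk towards the previous estimate. The dense metric
matters: the APC constraint couples the two surfaces and the coverages along
narrow ridges that a diagonal metric cannot absorb.

Initialisation sets the constant surface directions from crude data
summaries (mean observed prevalence; APC-implied mean consumption) and each
coverage from the ratio of the survey's censored-midpoint mean to the
APC-implied mean, because random initial points frequently violate the hard
APC coupling.

Two protocols are named: `paper` (11 chains x 10,000 iterations, 60%
warmup) and `test` (4 x 2,000, 60% warmup), the scaled protocol used by the
test suite and the analysis scripts. Convergence is checked with split-R-hat,
bulk ESS and the Monte-Carlo standard error per parameter (via arviz),
against thresholds R-hat < 1.05 and MCSE < 5% of the posterior sd.

Numerical notes: interval masses are differences of regularised incomplete
gamma functions, recomputed on the survival side when the difference
underflows (mass < 1e-9); probabilities are floored at 1e-300 before taking
logs; intervals with `lc = 0` never evaluate the density at zero (which
diverges for `alpha < 1`); degenerate tuples at exactly zero are rejected as
invalid input. Any parameter point producing a non-finite component returns
`-inf` to the sampler, which treats leaving the support as a divergence.

## Synthetic data generator

The generator emulates the study's data-generating process with known ground
truth, drawing from exactly the model family so that recovery failures
indicate implementation bugs rather than misspecification:

* truth surfaces bilinear in standardised year and age on the link scales —
  a strict subspace of every tensor-spline basis of dimension >= 2. Default
  means peak at ~41 (male) and ~23 (female) g/day, chosen so the 95th
  percentile of every cell stays below the 150 g/day cap (q95 ~ 3.4-3.5 mu
  at the default shapes) and the truth therefore lies where the model's own
  priors place mass;
* individual consumption Gamma with the sex-specific default shapes;
  reported consumption multiplied by `c'_s * c''_{g,a}` (true overall
  coverages 0.70 / 0.50 / 0.30, log-deviations up to 5%);
* interval censoring through a frequency-quantity category grid
  ({1-3/month, 1-2/week, 3-4/week, 5-7/week} x {1-2, 3-4, 5-6, 7+ drinks},
  12 g/drink), reduced to the non-overlapping partition its endpoints induce;
  one roster survey reports rounded weekly drink counts instead (degenerate
  intervals; a zero count becomes the left-censored interval "under one
  drink last week", keeping the likelihood proper);
* equal-size clusters with a small mean-preserving perturbation (sd 0.02) of
  the drinking propensity, so cluster-robust standard errors differ
  measurably from the SRS formula; lognormal sampling weights recalibrated
  to population totals;
* an APC series equal to the population-weighted truth total divided by
  `(1 - w)` plus N(0, 0.15) noise (grams/day per capita).

What the generator does **not** emulate: real questionnaire idiosyncrasies
(overlapping response categories, item nonresponse), informative
nonresponse, migration or mortality feedback on the population structure,
time-varying coverage deviations, and non-Gamma consumption shapes. Passing
recovery tests therefore demonstrate the correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation.

## Aggregation choices

Prevalence uses the weighted ratio estimator with a one-stage cluster
sandwich variance (with-replacement n/(n-1) factor); with equal weights and
independent records this reduces to `p(1-p)/(n-1)`. Effective sample sizes
follow a quality-effects redistribution: precision weights `1/pse^2` are
split into a retained part `q_s = bias_score/20` and a forfeited part
reallocated proportionally to precision, then the pooled raw sample is
distributed proportionally to the adjusted weights — conserving the pooled
total, rewarding both precision and quality. The redistribution is computed
within each sex-age cell by default; a per-survey mode (survey-level pooled
precision, cells filled proportionally to raw counts) is provided behind the
same interface.

## Scaled study conditions

The recovery study runs on a 5-year x 2-sex x 3-age-group grid with three
surveys of n = 2,000 (two frequency-quantity, one weekly-count), coverages
0.70 / 0.50 / 0.30 and w = 0.2, fitted with the `test` protocol across six
simulation seeds; each fit takes about 75 s on one CPU. Pooled across seeds
the 95% credible intervals cover the true cell means, prevalences and
survey coverages for well over 80% of cells, every fit passes the
diagnostics contract with zero divergences, and the posterior total
consumption sits within two posterior sds of `(1 - w) apc` in every year.

## Known limitations

* The weighted pseudo-likelihood treats `ne * pc` as exact counts; it does
  not propagate the sampling error of `pc` itself beyond the effective
  sample size.
* Posterior-predictive bands for surveys reporting exact drink counts are
  strict: the observed envelope collapses to a single empirical CDF whose
  sampling noise is not part of the predictive band, so band-coverage
  percentages for such surveys understate fit quality.
* The Laplace-seeded metric assumes a roughly Gaussian posterior bulk; on
  problems with multimodal posteriors the mode-finding step would need to be
  replaced by multiple dispersed optimisations.
* Coverage deviations `c''` are weakly identified when few surveys share
  them; their posteriors lean on the tight prior by design.
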