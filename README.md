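# alcmeta

Bayesian meta-regression that triangulates survey reports of alcohol use
with administrative per-capita consumption (APC) totals. It jointly
estimates, per year, sex and age group, the prevalence of current drinkers
and the Gamma-distributed daily consumption among drinkers, while
estimating each survey's *coverage* — the fraction of true consumption its
self-reports capture — inside the model.

Intended for alcohol-epidemiology researchers who need sex- and
age-specific exposure trends that are consistent with administrative
totals, with honest uncertainty on every derived quantity.

## The model

For drinkers in year *y*, sex *g*, age group *a*, daily intake (grams of
ethanol) is `X ~ Gamma(alpha_{y,g,a}, beta_{y,g,a})` with
`alpha = (mu/sd)^2`, `beta = alpha/mu`. Survey *s* observes `X * c_{s,g,a}`
with coverage `c_{s,g,a} = c'_s * c''_{g,a}` (an overall survey factor
times sex–age deviations with geometric mean one). Interval-censored survey
tuples `{lc, uc, pc, ne}` contribute `ne * pc * log P[lc <= X_obs <= uc]`;
prevalence estimates contribute `N(pp | p_{y,g,a}, pse)`; and each year the
population total obeys

```
sum_{g,a} mu_{y,g,a} * pop_{y,g,a} * p_{y,g,a} ~ N((1 - w) * apc_y, apcse_y)
```

with wastage fraction `w = 0.2` by default. `log mu` and `logit p` are
tensor-product thin-plate spline surfaces over year and age; informative
priors put the Gamma shape near 1.171^-2 ≈ 0.73 (males) and
1.258^-2 ≈ 0.63 (females) and make 95th percentiles above 150 g/day
extremely improbable. The posterior is sampled with a No-U-Turn Sampler
running on the exact gradient of the joint log posterior. See
`docs/methods.md` for the full account.

Because the real South African survey microdata are access-restricted, the
package ships a first-class synthetic-data generator (`alcmeta.synth`) that
emulates the whole data-generating process — Gamma consumption,
under-reporting, frequency–quantity censoring, cluster sampling, an APC
series — with known ground truth, so the entire pipeline is testable end to
end.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the synthetic
study (three surveys of n = 2,000 with true coverages 70% / 50% / 30%,
five years × two sexes × three age groups, w = 0.2):

```
$ python analysis/01_simulate.py 1
simulated 3 surveys, 6000 records total
true overall coverages: {'SYN-A': 0.7, 'SYN-B': 0.5, 'SYN-C': 0.3}

$ python analysis/02_preprocess.py
18 prevalence cells, 387 consumption tuples
pc sums within cells: min 1.000000000000, max 1.000000000000

$ python analysis/03_fit.py 1
3200 retained draws from 4 chains
max split-Rhat 1.0040, min ESS 2698, max MCSE/sd 0.019, 0 divergences -> PASS

$ python analysis/04_summarize.py
estimated survey coverage (truth in brackets):
  SYN-A: 63.2% (55.8-71.7) [70%]
  SYN-B: 47.3% (42.6-53.0) [50%]
  SYN-C: 27.1% (24.5-30.1) [30%]
final-year totals: prevalence 37.4% (35.5-39.4), mean consumption 28.1 g/day (26.5-29.8)
final-year males: heavy drinkers 16.3% of drinkers, 51.2% of the volume (mean 100.1 g/day)

$ python analysis/05_ppc.py
SYN-A: observed envelope intersects the predictive band at 100% of grid points
...
```

Reading the output: each survey's estimated coverage interval brackets or
approaches its simulation truth — the model attributes the gap between
reported and administrative totals to under-reporting, separately per
survey. The "final-year totals" row is the population-aggregated prevalence
of drinkers and mean consumption among drinkers with 95% credible
intervals, computed draw-by-draw. The heavy-drinker line illustrates the
concentration of volume: drinkers above the 60 g/day male threshold are a
sixth of drinkers but account for half the alcohol consumed.

The same pipeline is scriptable via the `alcmeta` CLI
(`simulate / preprocess / fit / summarize / ppc`, each taking `--config`,
`--seed`, `--w`, `--preset {test,paper}`), where the `paper` preset runs
the full-scale 11-chain × 10,000-iteration protocol.

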