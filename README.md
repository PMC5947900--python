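# stocksurv

Bayesian censored time-to-event analysis of **when commercially landed
marine stocks receive their first quantitative stock assessment**.

Most landed fish and invertebrate stocks have never had a full stock
assessment — a fitted population-dynamics model with explicit management
benchmarks — and assessment capacity is scarce.  Treating "years until
first assessment" as a survival problem lets one ask which stock
characteristics (landed tonnage, ex-vessel price, body size, habitat,
taxonomy, region, federal management-plan membership) drive the annual
probability of being assessed, whether that probability rises or falls
with elapsed time, and how the assessed fraction of each region's stocks
will evolve.  The intended users are fisheries scientists and analysts
prioritising data-limited stocks, and anyone needing a calibrated censored
Weibull hierarchical regression with nested categorical random effects.

## The model

For stock *i*, the time T from 1960 (or first landings, if later) to first
assessment is Weibull in the rate form,

    S(t) = exp(−λᵢ t^τ),      h(t) = λᵢ τ t^(τ−1),

with stocks unassessed by 2013 right-censored.  The log-rate is

    log λᵢ = β·Xᵢ + α_region + γ_habitat + κ_class + ω_order + ζ_family,

where Xᵢ holds log₁₀ price, log₁₀ maximum landings, their interaction and
log₁₀ maximum length, each standardized by twice its SD (plus an optional
raw 0/1 FMP indicator), and the categorical terms are exchangeable random
effects with half-Cauchy(100) scales.  β has Normal(0, precision 1e−5)
priors and τ a Gamma(1e−5, 1e−5) prior.  Coefficients read as hazard
ratios exp(β) or acceleration factors exp(−β/τ) on the median
time-to-assessment.  Posterior sampling is adaptive Metropolis-within-Gibbs
with specialised moves for the interceptless baseline and the
random-effect funnels; split-R̂/ESS are reported for every fit.  See
`docs/methods.md` for the full account.

## Worked example

A synthetic cohort with known truth, fitted and projected end to end
(about a minute on one core):

```python
import numpy as np
from stocksurv import (SimulationConfig, generate_stocks, build_event_table,
                       ModelConfig, sample_posterior, kaplan_meier,
                       weibull_shape_check, transform_effects,
                       project_proportion_assessed)

records, truth = generate_stocks(SimulationConfig(seed=1))
table = build_event_table(records)
print(f"{len(records)} stocks, {int(table.event.sum())} assessed by 2013")

slope, _, _ = weibull_shape_check(kaplan_meier(table.time, table.event))
print(f"KM log-log slope (empirical shape): {slope:.2f}")

post = sample_posterior(table, ModelConfig(seed=2))
tau = float(np.median(post.tau_flat()))
print(f"posterior median tau: {tau:.2f} (truth {truth['tau']})")
for j, name in enumerate(post.colnames):
    b = float(np.median(post.beta_flat()[:, j]))
    hr, _ = transform_effects(b, tau)
    print(f"  {name:17s} beta={b:+.2f}  hazard ratio={float(hr):.2f}")

proj = project_proportion_assessed(post, table, records, 2043)
for region in sorted(proj.draws):
    r = proj.for_region(region)
    print(f"  {region:10s} assessed 2013: {r['median'].iloc[0]:.0%}"
          f" -> projected 2043: {r['median'].iloc[-1]:.0%}")
```

prints

```
569 stocks, 246 assessed by 2013
KM log-log slope (empirical shape): 1.85
posterior median tau: 2.36 (truth 2.6)
  log10_price       beta=+0.82  hazard ratio=2.28
  log10_landings    beta=+1.04  hazard ratio=2.82
  price_x_landings  beta=-0.30  hazard ratio=0.74
  log10_length      beta=+0.55  hazard ratio=1.74
  Alaska     assessed 2013: 39% -> projected 2043: 75%
  Northeast  assessed 2013: 42% -> projected 2043: 77%
  Southeast  assessed 2013: 46% -> projected 2043: 75%
  WestCoast  assessed 2013: 46% -> projected 2043: 77%
```

Reading this: τ ≈ 2.4 > 1 means the annual assessment rate grows with
elapsed time; landings and price dominate (a two-SD increase in log
landings nearly triples the assessment rate); their negative interaction
says price matters most when landings are small.  The empirical KM slope
(1.85) sits below the fitted τ because between-stock rate heterogeneity
flattens the population-level hazard.  The projection rolls each
still-unassessed stock's Weibull clock forward conditionally on its
survival to 2013.

A YAML-driven pipeline and CLI wrap the same functions:

```bash
stocksurv simulate --n-stocks 569 --seed 1 --out stocks.csv
stocksurv fit stocks.csv --seed 2 --outdir fit_out
stocksurv diagnose stocks.csv --fitdir fit_out
stocksurv project stocks.csv --fitdir fit_out --horizon 2043
stocksurv run config.yaml        # any contiguous subset of stages
```

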