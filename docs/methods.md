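# Methods

## The question and the data structure

`stocksurv` models *when* a commercially landed marine stock receives its
first quantitative stock assessment.  The unit of analysis is a stock: one
species in one of four US regions (Alaska, West Coast, Northeast,
Southeast).  For each stock we observe the year of first recorded landings
(the landings database runs 1950–2013), the year of first assessment if one
occurred by 2013, a six-category habitat type, a class → order → family
taxonomy, species maximum length, and two economic covariates derived from
the landings record: maximum annual landings (t) and mean ex-vessel price
(US$/kg), both measured over years before the first assessment.

Because the first quantitative assessment on record happened in 1960, the
analysis clock starts at 1960, or at first landings if later:

    T_i = min(Ya_i − Yl_i, Ya_i − 1960),

with Ya the first-assessment year.  Stocks unassessed by 2013 are right
censored at their elapsed time in 2013.  A duration of exactly zero
(assessed in its origin year) is replaced by 0.5 years, since the Weibull
has support t > 0; the choice of a half year is arbitrary but affects only
a handful of degenerate rows.

## The model

Durations follow a Weibull distribution in the *rate* parameterization

    S(t) = exp(−λ t^τ),      f(t) = S(t) · λ τ t^(τ−1),

so the hazard is λτt^(τ−1): τ > 1 means the per-year assessment rate rises
with elapsed time.  (Beware the two common Weibull conventions: here λ is a
rate multiplying t^τ, not a scale inside (t/σ)^τ.  All downstream
transformations assume the rate form.)

The log-rate is linear in the covariates with one random effect per
categorical factor level:

    log λ_i = β·X_i + α_region(i) + γ_habitat(i) + κ_class(i)
              + ω_order(i) + ζ_family(i).

X_i holds the base-10 logs of price, landings, their interaction, and
maximum length, each standardized by **twice** its SD (so a coefficient is
the effect of a 2-SD change, comparable to flipping the binary FMP
indicator, which enters raw when enabled).  The interaction column is the
elementwise product of the two standardized main effects, itself
re-standardized by twice its SD so its coefficient sits on the same scale.

There is no global intercept: the factor effects are left uncentered and
jointly absorb the baseline rate.  For reporting, effects are centered to
sum to zero within each factor per draw (only deviations are identified);
order effects are additionally presented grouped under their parent class.

Censored likelihood: events contribute
`log λ + log τ + (τ−1) log t − λ t^τ`; censored stocks contribute the
log-survivor `−λ t^τ` only.

Priors: β_j ~ Normal(0, precision 1e−5); τ ~ Gamma(a = b = 1e−5); level
effects ~ Normal(0, σ_factor); σ_factor ~ half-Cauchy(scale Θ = 100).
The half-Cauchy is placed on the *standard deviation* (the conventional
weakly-informative construction that the Θ = 100 scale matches); a config
switch (`half_cauchy_on="variance"`) instead places it on the variance,
with the change-of-variables Jacobian so the sampled state remains the SD.

## Posterior sampling

Sampling uses an adaptive Metropolis-within-Gibbs scheme written in numpy
with all chains advanced in lockstep (vectorised over the chain axis).
Per iteration:

1. a log-scale random-walk step for τ;
2. a coupled (τ, baseline) "ridge" step: τ and the absorbed baseline are
   strongly negatively correlated (λ t^τ ≈ const), so log τ and a uniform
   translation of the first factor's effects are proposed jointly along
   that ridge (a deterministic translation per proposal, hence a symmetric
   kernel);
3. one random-walk step per regression coefficient;
4. per factor: a *blocked* update of every level effect (levels touch
   disjoint rows, so their accept/reject decisions are independent and
   exact), a mean-shift move translating the whole factor, a log-scale
   step for the factor SD, and a "funnel" move that rescales the effects
   and the SD together (the Gaussian quadratic term cancels against the
   Jacobian, so the move glides through the funnel that otherwise traps
   small-SD states);
5. pairwise exchange moves shifting baseline mass between two factors'
   means.  Only the *sum* of factor means enters the likelihood, so these
   moves are prior-only and mix the non-identified split cheaply.

Proposal scales adapt toward 44% acceptance in batches of 50 iterations
during burn-in only; the retained chain is therefore a valid
time-homogeneous Metropolis sampler.  The rate vector λ is cached and
updated incrementally, with a periodic full refresh against floating-point
drift.

The default protocol is 3 chains × 21 000 iterations, burn-in 1 000,
thinning 10 — 6 000 retained draws, chosen so a full study-scale fit runs
in well under a minute on one core.  `ModelConfig.full_protocol()` gives
the heavier 3 × 210 000 / thin 100 / burn-in 10 000 protocol (the same
6 000 retained draws).  Convergence is summarised by split-R̂ and bulk ESS
(via `arviz`) for τ, every β and every factor SD; a run with any R̂ above
the threshold (default 1.01) is returned flagged, never silently.

## Effect transformations

For a one-unit covariate change, the hazard ratio is exp(β) and the
acceleration factor — the multiplier on the median (or any quantile of)
time-to-assessment — is exp(−β/τ); they satisfy HR · AF^τ = 1 draw by
draw.  Marginal assessment-probability curves for a focal factor level use
that level's uncentered effect plus the per-draw mean of each non-focal
factor's effects (which carries the absorbed baseline) with continuous
covariates at their standardized mean of zero.

## Projections

The projected proportion of stocks assessed in region r by calendar year y
treats already-assessed stocks as contributing 1, and each unassessed
stock i (censored at elapsed time t₀ᵢ) as contributing

    p_i(y) = 1 − S_i(t₀ᵢ + y − 2013) / S_i(t₀ᵢ),

its conditional probability of first assessment by year y given it was
still unassessed at the censoring year.  Conditioning is the default —
the unconditional F_i(t_i(y)) would re-count risk the stock has already
survived — but an `conditional=False` flag provides the unconditional
variant for comparison.  Each stock's clock continues from its own origin,
so stocks differ in elapsed time at the same calendar year.  At y = 2013
the projection reduces exactly to the observed assessed fraction.

## Diagnostics

* **Shape check.**  If durations are Weibull, (log t, log(−log Ŝ(t)))
  from the Kaplan–Meier estimate is linear with slope τ.  The slope is fit
  by unweighted OLS over event times with 0 < Ŝ < 1 (the transform is
  undefined at 0 and 1).  Ties are handled with the standard convention
  (events before censorings); the KM computation is backed by
  `lifelines`.  Note the marginal KM slope on a heterogeneous cohort sits
  *below* the conditional τ of the regression model — unmodelled
  rate heterogeneity flattens the population-level hazard, so the
  empirical slope is expected to be smaller than the fitted shape.
* **Cox–Snell residuals.**  r_i = λ̄_i t_i^τ̄ at the posterior mean of the
  linear predictor and of τ, carrying the censoring flags.  Under a
  correct model the residuals are unit-exponential; the package reports
  the through-origin OLS slope of their KM cumulative hazard against r
  (target 1).  A per-draw variant is easy to add but the posterior-mean
  version is the default report.
* **Finite-population SDs.**  Per draw, the SD (denominator J − 1) of a
  factor's realized level effects — the variance each factor actually
  accounts for in this cohort, on a common scale across factors with very
  different level counts.

## The synthetic-data generator

`generate_stocks` emulates the statistical shape of the study cohort:
569 stocks; four regions and six habitats sampled uniformly; a nested
taxonomy (3 classes → 8 orders → 16 families, round-robin nesting);
log10 landings ~ N(2.0, 1.2) (median 100 t, heavy right skew), log10
price ~ N(0.3, 0.3) (median ≈ 2 $/kg), log10 length ~ N(1.65, 0.3)
(median ≈ 45 cm); first landings uniform over 1950–2000; true shape
τ = 2.6 and true coefficients (price +0.9, landings +1.1, interaction
−0.4, length +0.35 on the 2-SD scale) reproducing the fitted sign
pattern; random-effect SDs 0.2/0.25/0.5/0.5/0.4 for
region/habitat/class/order/family, putting more residual variance on
taxonomy than on region or habitat.  Because the model has no intercept,
the generator carries an explicit baseline log-rate; its default −10.2
was calibrated once so that the default cohort censors at ≈ 63%
unassessed, matching the study condition of roughly 37% of 569 stocks
assessed by 2013.  The FMP flag is drawn with probability 0.5 but its
effect defaults to 0 so that the default generating process matches the
default model (no FMP term); set `fmp_effect` > 0 to study the FMP
variant.

What the generator does **not** emulate: fishery-development dynamics in
the annual landings series (only the per-stock summary covariates are
drawn); correlation between covariates and taxonomy or region; measurement
error in habitat/length; the curation choices that define real stock
boundaries.  Passing recovery tests therefore demonstrate that the
inference machinery is correct and calibrated under the model's own
assumptions — not that the model is correctly specified for any real
cohort.

Assessment years are recorded as integers (rounded calendar years), so
fitted durations carry up to half a year of discretisation, as real data
would.

## Test and script problem sizes

The package's own checks run at sizes chosen to finish quickly on one
core: likelihood checks against closed forms on ~20 small instances; the
sampler against dense 450 × 450 grid integration on a two-parameter
reduction (n = 50); frequentist calibration over 20 replicate cohorts at
n = 569 with a light protocol (2 chains × 6 000, thin 5) — 95% intervals
cover truth for τ and each β in ≥ 18/20 and signs agree in ≥ 19/20;
shape-check recovery at n = 5 000; projections against forward Monte-Carlo
simulation on a 50-stock cohort at horizons +10/+20/+30 years.  The
acceptance script runs the full pipeline once at n = 569 with the default
6 000-draw protocol.

## Known limitations

* Pre-1950 landings and foreign-fleet catches bias the economic covariates
  for old fisheries; no correction is attempted.
* The covariate window for unassessed stocks ends at the last database
  year (configurable cutoff); the true future assessment year is unknown.
* Stocks with no usable price are imputed (species median, then global
  median) rather than dropped, to preserve the analysis n; imputation is
  logged.
* The interceptless parameterization leaves individual factor means
  unidentified; all reported factor effects are within-factor deviations,
  and the finite-population SD of a factor should be read with that in
  mind.
* Projections assume assessment priorities follow the fitted historical
  process indefinitely.
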