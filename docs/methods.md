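# Methods

## Cohort definition

One discharge record is one counted procedure. Inclusion requires ICD9-CM
procedure `81.51` in the principal or any of the ten secondary procedure
slots; a record with the code in several slots still counts once.
Exclusion requires any of the six diagnosis fields to start with `820`
after removing the dot, which covers 3-, 4- and 5-digit femoral-neck
fracture codes (`820`, `820.2`, `820.21`, …). Diagnosis fields never carry
procedure-format codes, so the dot-stripped prefix cannot collide with
procedure lookalikes such as `82.00`. Bilateral same-admission surgeries
are not disambiguated: the unit of analysis is the record.

Demographics tables always report margins recomputed from their cells.
The packaged published table's female column sums to 731,210 while its
printed total reads 731,200; we ship the cells and derive the margins, so
the 10-unit print discrepancy never propagates (the grand total, 1,318,400,
is unaffected).

Age classes follow the published demographics table (<45, 45–54, 55–64,
65–74, 75–84, >84). Population denominators use a parallel scheme with a
single `<50` class plus the ≥ 50 classes, because modelling restricts to
the resident population aged ≥ 50 (patients below 50 contribute a minimal
share of elective THA). In the hierarchical model the few <50 patients are
pooled into the lowest ≥ 50 stratum.

## Time index and the five likelihood models

All trend models use $t = \text{year} - 2000$, so the first training year
(2001) maps to $t = 1$; the logarithmic and power forms require $t \ge 1$.
Training spans 2001–2019: 2020+ is excluded to keep pandemic distortions
out of the fits.

* **LM** — binomial-logit rate model with the ≥ 50 population as
  denominator. At observed rates (~4 per 1,000) it nearly coincides with
  the Poisson model, a useful cross-check.
* **PM** — Poisson GLM with offset $\ln N_t$. Both GLMs are fitted with
  IRLS (statsmodels) and return Wald covariances.
* **LogM** — OLS of counts on $\ln t$; $\hat\sigma^2$ uses the residual
  degrees of freedom.
* **IP** — power law fitted as OLS of $\ln y$ on $\ln t$; the residual SD
  on the log scale drives the multiplicative prediction noise. Zero counts
  must be floored by the caller (the fit refuses them explicitly).
* **PLN** — the marginal likelihood integrates the yearly log-normal
  effect with **adaptive** Gauss–Hermite quadrature (30 nodes by default):
  nodes are recentred at the per-year mode of the integrand (Newton steps)
  and rescaled by its curvature. Plain fixed-node quadrature fails here —
  with counts of order $10^5$ the integrand's width in the standardised
  effect is $\approx 1/(\sigma\sqrt{y})$, far below the node spacing — and
  produces severely biased $\hat\sigma$. Optimisation runs Nelder–Mead
  then BFGS on $(\beta_0, \beta_1, \log\sigma)$ from a Poisson start; the
  covariance is the inverse numerical Hessian in $(\beta_0,\beta_1,\sigma)$.
  A solution with $\hat\sigma < 10^{-3}$ is flagged degenerate (the model
  has collapsed to PM) and inherits the Poisson covariance.

Self-consistency is enforced by tests: each model refitted on data it
generated recovers its parameters, and the standardised score at every
returned optimum is below $10^{-4}$.

## Hierarchical Poisson model with temporal effects

$$y_{a,t} \sim \mathrm{Pois}\!\big(N_{a,t}\, e^{\mu + \alpha_a + \gamma_t}\big)$$

with sum-to-zero age effects $\alpha_a \sim N(0, \tau_\alpha^2)$ and a
random-walk temporal effect ($\gamma_1 = 0$ anchors the level; RW(1) by
default, RW(2) available). Priors are weakly informative: $\mu \sim
N(0, 10^2)$, $\tau_\alpha \sim \mathrm{HalfNormal}(1)$, $\tau_\gamma \sim
\mathrm{HalfNormal}(0.2)$. The non-centred parameterisation samples the
standardised innovations.

Sampling uses the affine-invariant ensemble sampler (emcee): by default 4
independent ensembles of 64 walkers, 3,000 warm-up steps and ~3,000
retained steps thinned by 50, initialised from moderately jittered
empirical log-rates. Split-R̂ (arviz) is computed across the independent
ensembles for the scientific parameters $\mu, \tau_\alpha, \tau_\gamma$;
a fit exceeding the gate raises a hard `ConvergenceError` with the full
diagnostics rather than returning silently. The gate defaults to **1.02**:
for ensemble MCMC at these retained-draw sizes the slowest-mixing
parameter ($\tau_\gamma$) plateaus around R̂ ≈ 1.005–1.015 even at four
times the chain length, so a 1.01 gate (appropriate for gradient-based
samplers) would reject well-mixed fits; the threshold is configurable.

Forecasting extends $\gamma$ beyond the training window by the random walk
with zero drift. Consequently the forecast rate is flat in expectation and
the volume path tracks the projected age-specific populations — the
mechanism behind the rise-then-decline forecast when the ≥ 50 population
peaks mid-horizon.

## Prediction intervals and rate ratios

* **Analytic** (LogM): $\hat y_\ast \pm t_{0.975,\,n-2}\, \hat\sigma
  \sqrt{1 + 1/n + (\ln t_\ast - \overline{\ln t})^2 / S_{xx}}$, truncated
  at zero.
* **Parametric simulation** (LM, PM, IP, PLN): parameter vectors drawn
  from $N(\hat\theta, \hat\Sigma)$, pushed through the mean function, with
  observation noise from the model's family (binomial / Poisson /
  log-normal / Poisson-over-log-normal). Default 10,000 simulations;
  bounds are empirical 2.5/97.5 percentiles with linear interpolation
  between order statistics (type 7) — the convention used for every
  quantile in the package. The point forecast is the mean function at the
  estimate.
* **Posterior predictive** (HPTE): per retained draw, simulate the
  random-walk extension, draw Poisson counts per stratum from projected
  populations, sum strata.

Rate ratios divide a forecast's point and bounds by the **observed** (not
fitted) reference-year volume, 2019 by default — the last pre-pandemic
year anchors all growth statements. Taking percentiles of per-draw ratios
instead is implemented for sensitivity and coincides exactly when the
reference is a constant.

All three mechanisms are calibration-tested: empirical 95% coverage on
self-generated data, with pass bounds set by the exact binomial
Monte-Carlo band at the replicate counts used.

## Validation protocol

The seven-metric battery: MSE, RMSE, MAE; SD-SE (sample SD, $n-1$
denominator, of squared errors; defined as 0 for a single error) and
IQR-SE (type-7 quartiles of squared errors) for stability; RMSE and MAE
normalised by a data scale. The default scale is the **mean absolute
first difference of the training series** — the error scale of a naive
persistence forecast, as in MASE — because normalising by the mean level
would make all ratios tiny and incomparable across windows; any positive
scale can be supplied.

Rolling-origin internal validation uses an expanding window (defaults:
initial window 10 years, horizon 1, step 1 — nine folds on a 19-year
series; all configurable), never training past the 2019 cutoff. A fold's
fit failure is recorded for that model without dropping the fold for the
others. Out-of-sample validation trains once on 2001–2019 and scores
2020–2021 and 2022–2023 separately, isolating the pandemic shock from the
recovery.

## Synthetic registry

The generator is first-class, tested code that defines the study
conditions:

* **Population** (2001–2050): piecewise-linear trajectories per age class
  with staggered growth reversals so the ≥ 50 aggregate peaks in 2036 —
  the demographic turning point the hierarchical forecast must track.
  Levels are round numbers of order the national resident population.
* **Rates**: base rates calibrated so 2001 expected volume is ≈ 68k with
  the published age profile (modal class 65–74, ≈ 36%); female shares per
  class from the published margins; multiplicative trend 1.022/yr chosen
  so that, combined with demographic growth, 2023 volume is ≈ 1.8 × 2001
  (the published +80%). Shock multipliers: 0.84 in 2020 (the elective
  suspension), 1.07/1.05/1.03 in 2021–2023 (rebound above trend as
  postponed surgeries reschedule). A yearly log-normal perturbation
  (SD 0.03) adds the over-dispersion that motivates PLN.
* **Records**: one row per counted procedure with the registry layout
  (1 + 10 procedure, 1 + 5 diagnosis slots). ~20% of elective THAs carry
  `81.51` in a secondary slot; fracture-THA decoys (default 10% of the
  elective count) and non-THA distractors are added per year.
  Determinism: one substream per year derived from the seed, so files are
  byte-identical across reruns and stable under year reordering.

What the generator does **not** emulate: hospital identifiers, regional
structure, coding errors at realistic frequencies, readmissions/revisions,
and the exact curvature of the real volume series (ours grows
exponentially at a constant rate-trend; the real series is closer to
linear). Consequently passing tests demonstrate correctness of the
machinery and calibration of the statistics under the stated conditions,
not agreement of LogM/IP extrapolations with the published ones — those
depend on the real series' curvature.

For the pandemic-window error-pattern check (errors larger in 2020–2021
than 2022–2023 for every model) the test scenario uses stationary rates
(purely demographic, near-linear growth) with multipliers 0.84/0.96 and a
return to trend from 2022: with the default rebound-above-trend world, a
strongly misspecified trend model (LogM) can err more in the recovery
window than in the shock window, which is a property of the synthetic
curvature rather than of the protocol under test.

## Numerical conventions and limitations

* Quantiles: type 7 everywhere; SDs: $n-1$ denominator.
* Seeds: every stochastic routine takes an explicit seed; derived
  sub-streams stay below $2^{31}$.
* The IP and LogM forms are direct trend fits on raw counts (no
  population offset), consistent with their interval mechanisms; the
  binomial/Poisson/PLN forms carry the ≥ 50 offset. Alternative readings
  of the model family names (logistic growth curve, $a + b/t$ inverse
  form) are isolated behind the per-model fit functions and could be
  swapped without touching the pipeline.
* Wald intervals at $n = 19$ undercover slightly for the PLN slope
  (~92–93% empirical); small-sample $t$ quantiles mitigate but do not
  remove this.
* Ensemble MCMC mixes slowly on $\tau_\gamma$; the retained-draw sizes
  and the 1.02 gate reflect that. Reduced sampler settings used in
  replicate-heavy tests are honest but noisier; their acceptance bounds
  are exact binomial bands at the reduced counts.
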