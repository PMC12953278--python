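# Methods

## The model

`tempmort` estimates temperature-mortality associations per region with a
distributed lag non-linear model (DLNM) and projects them onto future
climate, adaptation and population scenarios.

Daily all-cause death counts `Y_t` are modelled as overdispersed Poisson:

    log E[Y_t] = alpha + cb(T, lag; theta) + ns(t; beta) + dow(t; gamma)

where `cb` is the cross-basis — the row-wise tensor product of a natural
cubic spline over daily mean temperature and a natural cubic spline over
lags 0..21 days — `ns(t)` is a natural cubic spline of the day index
controlling seasonality and the long-term trend, and `dow` is a set of six
day-of-week indicators (Monday reference; the contrast choice is absorbed
by the intercept and is immaterial).

The 21-day maximum lag reflects the long-lasting effect of cold in
high-latitude populations and accommodates short-term mortality
displacement (harvesting) after heat.  The model is fitted by iteratively
reweighted least squares under a Poisson likelihood; overdispersion is
estimated as Pearson chi-square over residual degrees of freedom and scales
the coefficient covariance (quasi-Poisson).

Two knot strategies are provided:

* **fixed knots** — exposure spline knots at the 10th/75th/90th percentiles
  of the region's fitting-period temperatures, lag spline with two internal
  knots equally spaced on 0..21;
* **qAIC knots** — a grid of exposure-percentile/lag-knot candidates scored
  by the quasi-AIC, `qAIC = -2*loglik + 2*p*phi` with `p` estimated
  parameters and `phi` the Pearson dispersion.  (The variant that divides
  the log-likelihood by `phi` instead of inflating the penalty is common in
  the literature; with the dispersions seen here the two rank candidate
  grids the same way in practice, and the penalty-inflation form is used
  throughout.)  Ties break toward fewer degrees of freedom, then toward the
  fixed-knots default.

## Reduction, centring and attribution

The fitted surface is reduced to the **overall cumulative** curve by
summing the lag-basis contributions over integer lags 0..21 (a linear map
`M`, so `coef = M theta`, `vcov = M V M'`).  Risks are expressed relative to
a fixed per-region **minimum-mortality temperature** (MMT, 14-16 °C across
the packaged Finnish county registry, southern regions warmer); the MMT is
taken from the registry, not re-estimated, so RR(MMT) = 1 exactly with zero
variance by construction of the centred contrast.

Daily attributable deaths follow the standard forward formulation

    AN_t = D_t * (1 - exp(-logRR(T_t)))

with the lag-summed curve applied to same-day temperature (no lag-resolved
backward attribution — the cumulative curve already integrates the lag
structure).  Days with `T > MMT` count as heat, `T < MMT` as cold; negative
AN is deliberately permitted where a fitted curve dips below RR = 1, as
several real counties show on the heat side.  Decade aggregates sum AN over
closed calendar decades (2010-2019 … 2090-2099); the attributable fraction
is AF = 100 * AN / (total deaths of the same days).  End-of-century change
is reported as the ratio of 2090s to 2010s AN, computed from unrounded
sums and rounded half-away-from-zero to one decimal; a non-positive
baseline leaves the ratio undefined.

## Uncertainty

Confidence intervals are **empirical Monte-Carlo** intervals: coefficient
vectors are drawn from a multivariate normal centred at the reduced-curve
estimate with its dispersion-scaled covariance (Cholesky root; eigenvalue
root with negatives clipped at zero as a logged fallback), decade AN is
recomputed per draw, and the 2.5th/97.5th percentiles (linear
interpolation) are reported.  One generator, seeded per run, is shared
across decades so draws are coherent in time.  For ensembles the point
estimate is the across-member mean and the interval pools each member's
draws, so it reflects both coefficient uncertainty and climate-model
spread; the combination rule for these two sources is a genuine modelling
choice (no canonical convention exists) and pooling was chosen as the
simplest rule that widens with member disagreement.

## Scenario layers

* **Climate**: ensembles of daily temperature series per emission scenario
  (moderate SSP2-4.5, high SSP5-8.5).  The synthetic pseudo-GCM members add
  a linear warming ramp (zero at 2015, full value at 2100) to a stationary
  seasonal series, with member end-of-century warmings spread over
  2.2-5.5 °C (moderate) and 5.8-9.1 °C (high).
* **Adaptation**: a stipulated proportional reduction `a` of heat-side
  excess relative risk, `RR' = 1 + (1-a)(RR-1)` above the MMT only, at
  levels 0%, 20%, 50%.  Scaling the excess (rather than RR or log-RR, which
  the source conventions leave open) keeps full adaptation at exactly
  RR = 1 and can never make heat protective; it is applied identically to
  point estimates and MC draws, as a constant level rather than a ramp.
* **Population**: future baseline deaths are the day-of-year climatology of
  observed deaths (Feb 29 imputed as the Feb 28 / Mar 1 mean) multiplied by
  a population factor — population linearly interpolated between 5-year
  anchors, divided by the baseline-year population.  Death rates are held
  at their reference proportion of population; no life-expectancy trend is
  modelled (a deliberate simplification).  AN is exactly linear in this
  factor and AF invariant to it.

## Synthetic data

The generator fabricates inputs with the structure the analysis assumes,
not a climate or demographic emulator:

* temperatures: annual mean 5 °C, seasonal amplitude 13 °C peaking near
  day 205, AR(1) noise (coefficient 0.7, innovation SD 2 °C) — a stylised
  southern-Finland series;
* deaths: log-rate = log(baseline 15/day) + a smooth low-amplitude secular
  term + day-of-week effects + the distributed-lag contribution of a
  V-shaped cumulative log-RR about MMT 16 °C (defaults RR 1.3 at MMT+10,
  RR 1.4 at MMT-20), with cold spread over lags by a slow geometric decay
  and heat front-loaded (an optional negative late tail emulates
  harvesting); counts are NB2 with variance = 1.5 x mean, the concrete law
  realising quasi-Poisson overdispersion;
* censoring: counts below 3 become missing, reproducing data-protection
  suppression; a region generated at 2 deaths/day loses over half its days
  and is excluded by the >50%-missing rule, mirroring the four excluded
  low-population counties;
* a 22-day burn-in is prepended so the analysis window has complete lag
  history.

The piecewise-linear V surface is intentionally the simplest shape with
identifiable heat/cold slopes for recovery tests; it is not in the spline
family the model fits, so recovery tests also probe approximation bias.
What the generator does **not** emulate: spatial correlation between
regions, influenza winters, heatwave clustering beyond AR(1) persistence,
demographic structure.  Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated data
model, not that real Finnish estimates are reproduced — the restricted
mortality data would be needed for that.

## Numerical choices

* Natural cubic spline basis: cubic B-splines constrained to zero second
  derivative at the boundary knots via the QR null space of the constraint
  matrix; outside the boundaries each column continues linearly (value and
  slope at the boundary), which is also the extrapolation contract for
  projected temperatures beyond the historical range — no clamping.
  Without an intercept the first natural column is dropped (the R `ns`
  convention).  Exposure boundary knots are the observed fitting-period
  min/max; percentile knots use linear interpolation between order
  statistics.
* Trend df: "7 degrees of freedom" is read as 7 df per year of series,
  rounded over the full span (126 columns for 18 years) — the standard
  seasonality control in this literature; total-df was the alternative
  reading.
* Missing-death days are dropped from the likelihood, but their
  temperatures still feed the lag windows of later days (the outcome is
  censored, the exposure is not).
* IRLS convergence: relative tolerance 1e-9, at most 100 iterations,
  non-convergence is an error.
* The first 21 days of a series lack a complete lag window and are
  excluded from the fit unless a leading temperature history is supplied.

## Problem sizes

Simulation-based checks in the test suite and acceptance script use
18-year series (the study length) for risk-recovery coverage at 50
replicates, 10-year series for null calibration, 5-year series for
qAIC-selection replicates, and 500-1000 Monte-Carlo draws; these sizes give
stable percentages while keeping a full run of suite plus script in the
low minutes on one CPU.

## Known limitations

* Day-of-year climatology of deaths assumes the seasonal mortality pattern
  itself is stationary; only its level scales with population.
* Adaptation is a constant stipulated level, not a ramp or an
  extrapolation of historical trends.
* No urban-heat-island adjustment, age stratification, cause-specific
  splits, or between-region pooling (BLUP/meta-regression) — each region is
  modelled independently.
* The qAIC candidate grid is a configurable default, not an exhaustive
  search.
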