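# Methods

## Model overview

`phenorisk` treats an insect's response to climate as a chain of
temperature-response functions evaluated against a year of daily
station weather. All temperatures are degrees Celsius; all rates are
per day; the calendar is a fixed 365-day year (leap days ignored,
day 1 = 1 January). The model is purely temperature-driven: rainfall,
humidity, diapause, host-plant quality, density dependence and
immigration/emigration are outside its scope, so its predictions are
upper-bound "climate suitability" statements, not population forecasts.

### Temperature responses

Each immature stage (egg, larva, pupa) carries three records:

* **Development rate** — Logan model,
  `r(T) = ψ[e^{ρ(T−T_b)} − e^{ρ(T_max−T_b)−(T_max−T)/δ}]`, clamped at 0
  and defined as 0 outside `(T_b, T_max)`. Unimodal for all shipped
  parameter sets (asserted on a 0.1 °C grid).
* **Whole-stage mortality** — `m(T) = min(1, e^{b₀+b₁T+b₂T²})`,
  interpreted as the probability of dying during the stage at constant
  temperature `T`.
* **Development-time variability** — a multiplicative individual
  factor with quantile function `exp(logit(u)/β)` (logit family;
  median exactly 1 because the intercept is fixed at 0) or
  `exp(ln(−ln(1−u))/β)` (complementary log-log, used for pupae).

Adults carry either a Stinner logistic longevity
`L(T) = c_max/(1+e^{k₁+k₂T})` (days) or a Hilbert–Logan senescence
rate `ψ[t'²/(t'²+d²) − e^{−(T_max−T)/δ}]`, `t' = max(0, T−T_b)`, whose
reciprocal is the constant-temperature lifespan. Lifetime fecundity is
`max(0, c₀+c₁T+c₂T²)` eggs per female, distributed over normalised
adult age `a ∈ [0,1]` by a gamma CDF renormalised at `a = 1` so any
partition of adult life sums exactly to the total.

Parameters are inputs, supplied as per-species YAML documents and
validated on load (missing stages or malformed records are rejected).
Estimating them from laboratory life tables is out of scope.

### Weather driver

Daily records are (tmin, tmax). Sub-daily temperatures follow a single
full-period cosine with the maximum at 14:00 and minimum at 02:00 —
the simplest phase-anchored choice; its 24-hour mean equals
(tmin+tmax)/2 exactly. The simulator can run on the 24 hourly steps
(default) or on daily means (faster, coarser). Warming scenarios are
additive monthly deltas to tmin/tmax; application is invertible by
negating the deltas, and a tmin/tmax inversion caused by differential
deltas is repaired by swapping, with a warning.

### Cohort simulation

A cohort of `n` eggs (default 2000; the library requires an explicit
seed) is laid at midnight on a start day and followed individually:

* **Development** by rate summation: individual `i` in stage `s`
  accumulates `r_s(T_step)·Δt / μ_{is}` until the sum reaches 1, where
  `μ_{is}` is one variability multiplier drawn per stage per
  individual. A relative slack of 1e−9 on the threshold prevents an
  exactly-divisible duration from spilling one step past a floating
  round-off.
* **Survival**: whole-stage mortality is converted to per-step
  survival `(1−m(T_step))^{Δdev}`, `Δdev` the fraction of the stage
  completed that step, so completing a stage at constant `T` implies
  survival exactly `1−m(T)`. Internally this is implemented by
  inverting the cumulative log-survival integral with a single uniform
  draw per stage — distribution-identical to per-step Bernoulli
  thinning but vectorisable. While development is halted (rate 0) no
  mortality accrues; individuals still immature at the 4-year horizon
  are censored as dead without reproducing.
* **Adults** form a female-based life table: all simulated individuals
  are treated as females and the sex ratio (default 0.5) enters once,
  scaling lifetime eggs to *female* eggs per female (`m_x`). Adult
  ageing is deterministic given weather: the daily senescence hazard
  (Hilbert–Logan rate, or `1/L(T)` for Stinner species, capped below
  at 1/400 per day) is rate-summed until it reaches 1, which at
  constant temperature reproduces the longevity curve exactly. Eggs
  are laid day by day following the gamma age profile over the
  realised lifespan, with fecundity evaluated at the mean daily-mean
  temperature of the adult's life.

From the daily schedule: `R₀ = Σ l_x m_x`, `T = Σ x l_x m_x / R₀`,
`r_m` solves `Σ e^{−r x} l_x m_x = 1` by a bracketed Brent solve
(residual < 1e−10), `λ = e^{r_m}`, `DT = ln 2 / r_m`. An extinct
cohort (no female egg) is data, not an error: `R₀ = 0`, rate
parameters `None`, `extinct=True`.

`rm_profile` evaluates `r_m` on a strictly increasing constant-
temperature grid and interpolates linearly; non-viable nodes take a
configurable extinction floor (default −0.5/day). Queries outside the
grid are clamped with a warning.

### Risk indices

The verbal index definitions are fixed here in algebraic form:

* `ERI = (1/365) Σ_d Π_s (1 − m_s(T̄_d))` with `T̄_d` the daily mean —
  bounded in [0, 1], monotone non-increasing under any pointwise
  mortality increase.
* `GI = 365 / mean(T_launch)` over cohorts launched on the first day
  of each month (launch seeds are `seed + launch index`); extinct
  launches are excluded, and GI = 0 if all twelve are extinct.
* `AI = (1/ln 10) Σ_d max(r_floor, r_m(T̄_d))` — log₁₀ of the year's
  multiplicative growth. The floor (default −0.1/day) keeps lethal
  days from driving the sum to −∞; the daily finite-rate series
  `λ_d = exp(max(r_floor, r_m(T̄_d)))` reproduces AI as `Σ log₁₀ λ_d`
  exactly.

ERI and AI deliberately run on daily means (index lookups); GI runs
the full hourly simulator. Synchrony is host ERI minus parasitoid ERI
at matching stations or on matching grids — an index difference only,
with no population-dynamic coupling.

### Spatial interpolation

Station indices are interpolated by a 2-D thin-plate spline in planar
map coordinates with kernel `U(r) = r² ln r` (`U(0) = 0`) and an
affine trend `a₀ + a_x x + a_y y + a_z z` in which DEM elevation `z`
enters as a linear covariate — the standard augmented system with the
four orthogonality side conditions on the kernel weights. A full 3-D
spline in (x, y, z) was deliberately not used: with ~6 stations per
transect the linear-covariate trend is the most defensible reading,
and smoothing defaults to 0 (exact interpolation) for the same reason.
Duplicate or collinear station layouts raise a descriptive error
rather than a silent near-singular solve.

Rasters are ESRI ASCII grids (keywords ncols/nrows/xllcorner/
yllcorner/cellsize/nodata_value; case-insensitive read, lower-case
write, 6 significant digits — round-trip lossless at that precision).
Point sampling is nearest-cell with a round-half-up corner tie-break
(the east/north cell wins). Altitude profiles partition valid cells
into equal-width elevation bins over [min, max]; empty bins are
reported as missing.

### Yield loss

Zone bands are lower-inclusive, upper-exclusive, with the top band
unbounded. OLS (via statsmodels) of observed zone losses on zone-mean
AI reports β₀, β₁, their standard errors, F, t, p and R². With the
default four zones the fit has one residual degree of freedom, so a
low-n warning is always logged; note that a 2-standard-error interval
under a t(2) pivot covers the truth only 81.6% of the time, so the
replication study in the tests uses a longer index grid where the
two-SE convention has close to its nominal coverage. Predictions are
raw linear values — negative losses are logged, never clamped —
because the change tables difference them linearly.

The bundled reference tables (observed zone losses, reported
coefficients and predicted losses for the Kilimanjaro and Taita Hills
transects) support desk checks: inverting predictions through the
reported coefficients recovers the per-zone activity indices, making
the predictions exact forward evaluations. Refitting from those
inverted indices reproduces the coefficients only to ~0.01–0.02
because the predictions are printed at two decimals; that rounding,
not the estimator, is the precision floor.

## The synthetic generator

`make_transect` emulates a transect field design — six stations spanning
700–1800 m — with daily mean temperature
`base + lapse·alt/1000 + A·cos(2π(day−46)/365) + ε`,
`tmin/tmax = mean ∓ diurnal_range/2`. Defaults: sea-level base 28 °C
(giving 23.4 °C at 700 m and 16.4 °C at 1800 m, matching the reported
transect ranges), lapse −6.5 °C/km (standard atmosphere; adjacent
stations then differ by ≈1.4 °C), seasonal amplitude 2 °C with the
warm peak in mid-February, diurnal range 10 °C, Gaussian noise
1 °C/day. A single annual harmonic is used: the bimodal East African
seasonality is a rainfall feature, and rainfall is out of scope (a
second harmonic can be enabled). The DEM is a one-sided, mildly convex
west-to-east slope with a gentle cross-ridge so station layouts are
never collinear; stations sit at the cells matching their altitudes
within one cell's relief.

The four species profiles are *qualitative* emulations: development
optima ~30 °C (lowland) vs ~24–25 °C (highland), mortality minima
placed warmer (26 °C) for the lowland host and cooler (17 °C) for the
highland host so establishment rises toward, respectively, the bottom
and the top of the gradient, and parasitoids with 2–3× shorter
immature development than their hosts. No fidelity to any laboratory
parameter estimate is claimed; what the passing tests show is that the
*pipeline* reproduces the expected qualitative geography (altitudinal
partitioning of hosts, faster parasitoid cycling, uniform positive
warming response below the thermal optimum), not that these parameters
describe the real species. The warming scenario defaults to +1.45 °C
with a ±0.45 °C seasonal cosine (range 1.0–1.9 °C). Synthetic observed
losses are `β₀ + β₁·AI + N(0, 2)` clamped at ≥ 0; the demo's true
coefficients (β₀ = 30, β₁ = 1.5) are chosen on the demo transect's own
AI scale so the clamp never binds and the linear relation is actually
recoverable.

## Problem sizes and numerical choices

Demo and acceptance runs use cohorts of 200 individuals, an `r_m` grid
spaced 1.5 °C across the transect's (current ∪ future) daily-mean
range, and the 48×36-cell DEM; the full pipeline completes in a few
seconds. Defaults elsewhere: cohort size 2000, hourly driver,
extinction floor −0.5/day for profiles and −0.1/day inside AI,
mortality clipped at 1−1e−12 before the log, 4-year simulation
horizon, 400-day adult-lifespan cap. Every stochastic component is a
pure function of its seed (GI launches use `seed + i`, the demo's loss
noise `seed + 7919`).

## Known limitations

* Temperature-only: no rainfall/humidity terms, no diapause, no
  density dependence, no dispersal; synchrony is an index difference,
  not an interaction model.
* The exact functional variants used by other phenology-modelling
  software (Logan type I vs III, Stinner sign conventions, whether
  establishment indices are survival-normalised, weekly vs monthly
  generation launches) are not uniquely determined in the literature;
  the forms fixed above are declared normative for this package rather
  than asserted as identical to any other implementation.
* Adult ageing and oviposition are deterministic given weather;
  stochasticity lives in immature development and survival.
* Four-zone regression inference is fragile by construction (df = 1
  in the reported two-transect fits, df = 2 here); treat the reported
  p-values as descriptive.
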