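# Methods

## Scope and structure

The package projects incident cases of air-pollution-related
non-communicable diseases and the associated health and social care
costs for an England-like population under counterfactual exposure
scenarios. It is organised as a fit/results pair: `PollutionMicrosim`
binds the input *world* (exposure distributions, disease and cost
tables, life table, population structure) to run settings; `fit()`
completes the epidemiological tables and calibrates reference-level
hazards, and the returned results object simulates scenarios and feeds
the reporting layer. Exposure handling, rate completion, the annual
simulation loop, cost accrual and reporting live in separate modules
behind that surface.

## Exposure

Concentration surfaces carry a total and a natural (non-anthropogenic)
component per grid cell, with natural ≤ total everywhere. Source-year
surfaces are brought to 2015 by flat rural-background offsets of
−1.2 μg/m³ (PM2.5) and −2.3 μg/m³ (NO2), floored at the natural
component. Population points take the value of the nearest cell
centre; exact midpoint ties resolve to the lower x, then lower y,
centre (the intersection rule had to be fixed somewhere; nearest-cell
with a deterministic tie-break is the simplest auditable choice).

Within each (5-year age band, sex) stratum, population-weighted
concentrations are split into three equal-weight tertiles — points
straddling a boundary have their weight divided — and each tertile is
summarised by a weighted empirical quantile function on a 101-point
percentile grid. Tertiles are defined per stratum, not nationally.
The grid points act as equal-probability atoms: a person's uniform
percentile selects one atom, so the expectation of any function of
concentration over the distribution equals the plain mean over grid
values. This discrete representation is used consistently by the
hazard calibration and the simulation engine, which makes the
calibration identity exact rather than approximate.

Each person draws a tertile (by stratum weight) and a percentile at
creation and keeps both for life; aging only changes which stratum's
quantile function the rank is mapped through.

Scenario counterfactuals act pointwise on the total-concentration
quantiles: replacement by the natural distribution, subtraction of δ
floored at the natural level, or capping at a limit L (also floored at
the natural level, which only matters if L were set below natural).
All transforms are monotone and idempotent where expected. The NO2
natural level is fixed at zero — most NO2 is anthropogenic and no
natural-component data are modelled — so the natural counterfactual
sends NO2 exposure to zero. The "1 μg/m³ reduction in 2017" scenario
is a sustained shift from 2017 onwards, not a one-year dip: avoided
cases keep accruing to 2035 only under a sustained change.

## Exposure–response and calibration

Published odds, hazard and risk ratios per 10 μg/m³ are all treated as
rate ratios on the annual incidence hazard h = −ln(1 − p): hazards are
multiplied and back-transformed, which keeps annual probabilities
below 1 at any exposure. NO2 estimates are first reduced by 60% of
their excess risk on the linear scale (1 + 0.4·(ER − 1)) to account
for overlap with PM2.5 effects; the linear reading is the closest
match to "reduced by 60% from the published values", and the
alternative log-scale reading differs only in the third decimal at
these effect sizes. Missing pollutant–disease estimates mean a
multiplier of exactly 1.

The attribution reference is each person's natural level at their own
quantile, so the multiplier acts on the anthropogenic increment
(C − C_nat)/10. Scenario comparisons are invariant to this choice
because both arms share it.

Reference-level hazards are calibrated per disease, age and sex as
h₀ = observed incidence / E[RR], with the expectation taken over the
stratum's tertile-weighted atom distribution; pollutant assignments
are independent so the two-pollutant expectation factorises. By
construction the baseline arm then reproduces the observed incidence
in expectation (verified by simulation in the test suite).

## Rate completion

National sources publish different subsets of rates per condition.
Missing cells are derived by single-year-age cohort bookkeeping in the
style of the WHO DISMOD II equations. With p(a) prevalence, f(a) case
fatality, μ(a) other-cause mortality and i(a) incidence among the
disease-free, the annual step is

    p(a+1) = [p(a)(1 − f − μ) + (1 − p(a))·i] / [1 − μ − p(a)·f]

Case fatality comes from f = m/p (condition mortality over
prevalence); incidence comes from inverting the step above. The
forward recursion is the exact inverse of the completion, so
round-trip recovery is limited only by floating point (the tests
assert 2% to leave headroom for less regular tables). Implied negative
incidence or f > 1 raises an error naming the offending age. Lung
cancer's {1, 5, 10}-year survival is converted to a piecewise-constant
annual case fatality by geometric interpolation within each interval,
applied by years since onset; beyond 10 years the last annual rate
persists. Type 2 diabetes and low birth weight are non-terminal and
carry no excess mortality.

## Simulation engine

Annual cycle, fixed event order: incidence draws, then mortality
draws (condition case fatality, then other-cause), then aging and
births. The order is arbitrary but fixed and documented because it
affects small-sample results. Other-cause mortality is the all-cause
life-table probability minus the modelled conditions' mortality,
floored at zero, preventing double-counted deaths. Multiple concurrent
conditions are allowed; hazards are independent given exposure and
costs are additive across conditions. Disease states are initialised
at 2015 from the completed prevalence tables (independently of
exposure); lung cancer starts disease-free because its prevalence is
not an input and its costs are per-death anyway.

Birth cohorts are sized to hold the age-0 population constant
(stationary demography) rather than projecting fertility — a
deliberate simplification in place of unavailable demographic
projections. Low birth weight is drawn once per birth from a randomly
selected mother aged 15–49, using the mother's exposure multiplier on
the calibrated per-birth baseline probability; it is recorded as
incidence (prevalence is taken as equivalent) and carries no cost.

Every replicate uses the stream `seed + replicate`; draws are made for
every person slot in a fixed order independent of scenario, so two
scenario arms with the same seed are draw-for-draw aligned (common
random numbers). Differences of replicate arrays therefore isolate the
scenario effect; differenced cells may still be negative in noisy
cells (e.g. a person who dies of CHD at baseline but survives in the
counterfactual can later acquire another disease there) and are
reported as-is. Outputs are scaled by reference population over
simulated population, with normal-approximation Monte Carlo intervals
mean ± 1.96·sd/√R; these reflect simulation noise only, never input
uncertainty, and are undefined (NaN) for a single replicate.

## Costs

Four care categories per condition, in GBP per prevalent case-year at
2015 values; palliative entries (all four lung-cancer categories;
social care for asthma, COPD, stroke and diabetes) are per death
instead. Costs accrue from the onset year inclusive; per-death costs
accrue in the year of death. Outputs are discounted to 2015 (the cost
base year) at 1.5%/year, the same flat rate used to represent
HCHS-style inflation of the cost inputs. Low birth weight has no cost
inputs and contributes zero, logged once. Two report variants filter
on evidence strength: dementia and low birth weight are classed as
weaker evidence, all other conditions as strong.

## Synthetic world

The generator produces every pipeline input with the statistical
structure the analysis assumes, not geographic realism:

* **Surfaces** — spatially correlated log-normal fields (Gaussian
  smoothing of white noise, renormalised). Defaults are sized so
  post-extrapolation PM2.5 sits near ~10 μg/m³ (log-sd 0.22) with a
  ~1 μg/m³ natural dust/sea-salt floor, and NO2 near ~23 μg/m³
  (log-sd 0.40) so the 40 μg/m³ cap binds in the upper tail. The
  natural component is an independent low-variance field clipped to
  [0, total] — a floor, not a geochemical model.
* **Points** — uniform locations with log-normal population weights
  (postcode-centroid stand-ins, ~40 persons each); every point carries
  the national age/sex structure, so strata differ in weight but not
  concentration mix.
* **Population** — a smooth 2015 England-like pyramid; ages uniform
  within 5-year bands (90+ treated as 90–99); reference population
  54,786,300.
* **Life table** — Gompertz–Makeham with an infant bump; female rates
  below male.
* **Disease tables** — ground-truth incidence and case-fatality curves
  at England-like orders of magnitude, forward-simulated to
  prevalence/mortality, then blanked to the cells a national source
  would publish, so internal consistency holds by construction and
  every condition shows non-zero incidence in a 100k-person run.
  Exposure–response defaults are the published central estimates per
  10 μg/m³.

What the synthetic world does **not** emulate: real spatial
correlation between exposure and demography, within-stratum age
structure of exposure, socioeconomic gradients, exposure measurement
error, or real English rates. Passing tests therefore demonstrate the
correctness and internal consistency of the machinery — calibration
closure, oracle equivalence, accounting identities — not agreement
with observed English burden; the published reference estimates are
reproduced arithmetically through the reporting identities, not
re-derived from raw inputs.

## Numerical choices and problem sizes

* Percentile grid: 101 atoms per tertile; empirical quantiles are
  type-1 (left-continuous step).
* Hazard transform uses `log1p`/`expm1`; probabilities are clipped
  below 1 − 1e−12 before exponentiation.
* Exposure distributions shift by at most the quantile representation
  error under transforms; all transform identities are exact.
* Desk defaults: 100,000 individuals, 10 replicates (the CLI default
  is 5); the reproduction script uses 50,000 individuals, 5
  replicates and a 1,500-point surface intersection. These sizes give
  Monte Carlo standard errors small enough for every 3-SE property
  check while keeping a full multi-scenario comparison to seconds.
* Statistical property tests use pre-registered seed sets and bands
  sized to ≈3σ of the estimator (e.g. the √2 Monte Carlo shrinkage
  check uses 40 seeds and accepts a standard-deviation ratio in
  (1, 2)); with fixed seeds they are deterministic.

## Known limitations

Annual averages only (no short-term peaks); flat future exposure
trends; no migration; no remission except the non-terminal conditions;
no comorbidity interactions beyond additive hazards and costs; no
propagation of input uncertainty (exposure–response confidence
intervals enter only as central estimates); cost inputs are per-case
averages, not utilisation models; the per-death social-care entries of
the non-terminal diabetes row can never accrue (diabetes has no
modelled deaths) — a faithful consequence of the input table's flags.
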