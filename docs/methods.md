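# Methods

## Scope and model structure

`aedespop` simulates *Aedes albopictus* abundance at a single temperate
site from daily weather.  The causal chain is: weather → habitat drivers
(daylength, container water temperature, soil water) → stage-structured
population ODEs → expected weekly trap captures.  Everything downstream of
the weather file is deterministic; stochasticity enters only through the
Poisson observation model and the synthetic-data generators.

The five stages are active eggs, diapausing eggs, larvae, pupae and adult
females.  Females only: the trap data the model is built for (CO₂-baited
dry-ice traps) capture host-seeking females, so oviposition is expressed
as female eggs per female per day.  Density dependence acts on larvae
alone, through the crowding rate `L/K`; captures are assumed not to
deplete the population.

## Environmental drivers

**Photoperiod.**  Astronomical sunrise-to-sunset daylength by the standard
solar-position algorithm: Spencer Fourier-series declination and the
sunrise hour angle at a solar zenith of 90.833°, which folds in
atmospheric refraction and the solar radius.  Polar day/night return 24/0.
The day-to-day change δD gates the diapause terms; its first element
copies the second so the gates never see an undefined sign.  The weekly
cues `D_week`, `Ta_week`, `Tw_week` are trailing 7-day means (current day
included); before day 7 the mean of the available history is used.

**Water temperature.**  Containers of a few litres track air temperature
with a small radiative offset.  Each day an equilibrium temperature is
computed from a linearised energy balance — absorbed shortwave
`(1 − albedo)·S`, net longwave loss `35·(0.34 − 0.14√e_a)·(1 − 0.8·cloud)`
(MJ m⁻² day⁻¹, Brunt-type humidity dependence), and a latent term
proportional to the vapour-pressure deficit with a linear wind function —
divided by a bulk exchange conductance `10 + 2·wind` MJ m⁻² day⁻¹ K⁻¹.
Water relaxes toward this equilibrium at 0.6 day⁻¹ and is floored at 0 °C.
The offset is typically +0.5 to +1.5 °C in summer and near zero under
overcast, humid, calm conditions.

**Soil water.**  A single bucket of capacity `W*` (default 150 mm).
Precipitation falls as snow below 0 °C; snow melts at 3 mm °C⁻¹ day⁻¹.
Potential evapotranspiration is Thornthwaite's temperature method (monthly
climatological means, annual heat index), with each month's total
distributed over its days in proportion to daylength and zeroed on days
with Ta ≤ 0 °C.  Actual evapotranspiration scales PET by the bucket fill
`W/W*`; inflow beyond capacity leaves as overflow.  The ledger (rain,
snow, melt, AET, overflow) closes the mass balance to rounding error by
construction, which the tests verify over a century of synthetic weather.
The bucket starts full (wet-winter start) with no snowpack.

## Thermal responses

Development (egg, larva, pupa) uses Brière curves
`c·T·(T − T_min)·√(T_max − T)` on (10, 38) °C; oviposition a symmetric
quadratic on (10, 40) °C peaking at 25 °C; mortality U-shaped
`m_min·exp(((T − T_opt)/s)²)`, floored at the stage's optimum and **capped
at 1 day⁻¹** — mortality faster than that is not resolvable under daily
forcing, and the cap keeps every linear rate inside the stability region
of the daily integration step.  Defaults are literature-informed and
field-leaning: stage durations of roughly 7/10/3 days at 25 °C, mortality
floors of 3–4 %/day (aquatic) and 10 %/day (adults), oviposition peaking
at 2 female eggs female⁻¹ day⁻¹.  An earlier, laboratory-leaning draft
(lifetime fecundity ≈ 150) produced equilibrium larval crowding of
~13 day⁻¹, outside the stable range of a daily RK4 step and far above
field recruitment; the moderated set is both numerically sound and closer
to field demography.  All curves are plain parameter objects and fully
overridable; no result in this package depends on their exact values.

## Diapause gates

Both gates are products of two logistic terms, computed with `expit` so
slopes up to 10⁶ cannot overflow; outside their photoperiod-trend
condition (δD < 0 for induction, δD > 0 for termination) they are exactly
zero — the complementary flux must vanish for the winter/summer logic to
work.  An alternative hard-threshold mode (`threshold_diapause`, defaults
21 °C / 13.5 h for induction and 10.5 °C / 10.25 h for break) is provided
for comparison with switch-type diapause formulations.

Note an identifiability property of the product form: around the week the
gate flips, only the *later-binding* cue is pinned by abundance data.  At
Tokyo-like sites the two spring cues cross their thresholds in the same
week, which is what makes both β_d2 and β_t2 estimable; the synthetic
truth reproduces this coincidence (see below).

## Integration

Classical RK4 with the day's environment held constant, one step per day
by default (`dt` configurable; `dt = 0.1` serves as the convergence
oracle in the tests).  States are clamped at zero after each day; a
non-finite state aborts with the offending date.  The gate probabilities,
carrying capacity and thermal rates are state-independent, so they are
precomputed per day and the inner loop is numba-compiled — a nine-year
forward run costs ~0.5 ms, which is what makes annealing affordable.
Measured accuracy of the daily step against the 10× finer oracle is
2–3 × 10⁻³ (relative to each stage's annual maximum).  The dominant error
is irreducible at dt = 1: fitted gate slopes saturate z₂ to 1, so the
spring hatch drains the diapause pool at 1 day⁻¹, a rate at which a single
daily RK4 step carries ~1.9 % truncation.  Sub-daily stepping removes it
(dt = 0.5 gives ~10⁻⁴) at proportional cost.

Simulations start January 1 with 1000 diapausing eggs and nothing else —
overwintering happens in the egg bank — and the first simulated year is
excluded from likelihoods and summaries as burn-in.

## Calibration

Weekly counts are Poisson with mean `capture_rate ×` (7-day mean of A),
weeks being 7-day blocks from January 1; the expectation is floored at
10⁻⁹ to keep the likelihood finite during simulated extinctions.  Nine
parameters are free by default: κ_max and the four slopes in log10 space,
the four half-saturation points linear, with β_t1 bounded above by 30 °C.
The sampler is a Metropolis random walk with joint Gaussian proposals,
acceptance `min(1, exp(Δℓ/T))`, and a geometric temperature ladder
(60 levels × 200 proposals, cooling 0.95).  If no initial temperature is
given, it is set so that roughly half of the starting proposals would be
accepted (median |Δℓ| of a probe sample ÷ ln 2).  Out-of-bounds proposals
are rejected outright; the best-ever candidate is returned; runs are
bit-reproducible given the seed.  On eight years of synthetic counts the
default schedule recovers β_d1 and β_d2 to ±0.3 h and κ_max to ±15 %
(three of three test seeds), in ~15 s per run.

## Scenario summaries

A trajectory is reduced to weekly mean adults per year, averaged across
years by week; the peak of that averaged series and its (earliest) argmax
week are the scenario's headline numbers, and the active season is the
span of weeks at or above 5 % of the peak (the threshold is configurable;
no standard definition exists).  `compare_models` is the peak ratio
between two runs, to two decimals; `compute_bias` is the same ratio
between two climate inputs under one parameter set, and correcting a raw
cross-model ratio for climate-input bias is plain division.  Driver
histograms give precipitation a dedicated exact-zero bin (dry-day
frequency is the feature that differs most between observed and
climate-model rainfall) and 5-mm / 5-percentage-point bins otherwise.
`scenario_shift` emulates emission-scenario forcing as a uniform warming
offset plus a wet-day precipitation multiplier — deliberately simple; it
does not reproduce changed rainfall *frequency*.

## Synthetic data

The weather generator is the package's study-conditions definition, not a
tuning knob: a seasonal air-temperature sinusoid (mean 16 °C, amplitude
10.5 °C, peak DOY 220) with AR(1) noise (ρ = 0.7, σ = 1.5 °C);
two-state Markov rain occurrence (p_wet|dry = 0.25, p_wet|wet = 0.55,
stationary wet fraction ≈ 0.36) with gamma amounts (shape 0.8, scale
14 mm; ≈ 1500 mm yr⁻¹) — zero-inflated and right-skewed, as daily
rainfall is; humidity, radiation, wind and cloud as clipped seasonal
sinusoids plus noise, cloudier and more humid on wet days.  It emulates
Tokyo's climate statistics, not its weather records: no fronts, typhoons,
or rainfall seasonality, and a symmetric annual temperature cycle whose
March runs ~2 °C cooler than the real city.  Consequences of that last
point: the synthetic week-10 water temperature is ≈ 7 °C, so the
synthetic truth sets the termination temperature threshold β_t2 = 7 °C to
reproduce the real-site coincidence of the two spring cues (at the actual
site the fitted β_t2 equals the local week-10 water temperature).  All
other truth parameters are the package defaults.  Trap counts are drawn
Poisson around the noiseless forward run, so every calibration test knows
its generating truth exactly.  Passing these tests shows the machinery is
correct and the parameters are identifiable under realistic seasonal
forcing; it does not validate the model against real mosquito data.

## Numerical choices and edge cases

* Carrying capacity floored at 10⁻⁶ (a negligible dry-soil refuge) so the
  crowding term stays finite at `W = 0` with ν > 0.
* Expected captures floored at 10⁻⁹; counts validated as nonnegative
  integers, one per year-week.
* Sigmoid exponents evaluated through `expit`; no explicit exponentials.
* Weekly peak ties resolve to the earliest week.
* Years with fewer than 365 simulated days are excluded from summaries
  with a warning.
* CSV floats are parsed round-trip-exactly so written fixtures
  re-simulate bit-for-bit.

## Limitations

Single site, no dispersal or immigration; no gonotrophic-cycle or
host-seeking behaviour (capture rate is a fixed 1 %); density dependence
only in larvae; diapausing eggs suffer no mortality; the habitat
sub-models are deliberately minimal (one bucket, one container, no
container-level evaporation); thermal-response defaults are plausible but
not fitted to any laboratory data set shipped here.  Projections inherit
all of these, plus the usual caveat that fitted diapause cues are
site-specific and assumed invariant under climate change.
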