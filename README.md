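# aedespop

Climate-driven population dynamics of the Asian tiger mosquito,
*Aedes albopictus*, for temperate sites where the species overwinters as
diapausing eggs.  The package is aimed at vector ecologists and
climate-health modellers who want to fit a mechanistic abundance model to
weekly adult trap counts and project it under altered climate forcing —
in particular, to ask how much the *rainfall* pathway (habitat soil
moisture driving larval carrying capacity) changes those projections.

## The model

Daily weather drives five stage abundances — active eggs `E`, diapausing
eggs `E_dia`, larvae `L`, pupae `P`, adult females `A`:

```
dE/dt     = (1 − z₁) o_v A − (m_E + d_E) E + z₂ E_dia
dE_dia/dt = z₁ o_v A − z₂ E_dia
dL/dt     = d_E E − (m_L + d_L + L/K) L
dP/dt     = d_L L − (m_P + d_P) P
dA/dt     = d_P P − m_A A
```

with temperature-dependent development rates `d_i` and mortalities `m_i`
(aquatic stages respond to container **water** temperature, adults and
oviposition `o_v` to air temperature) and a larval crowding term `L/K`.
Two environmentally gated probabilities control overwintering:

* diapause induction `z₁ = σ(α_d1(β_d1 − D_week)) · σ(α_t1(β_t1 − Ta_week))`,
  active only while days shorten (δD < 0);
* diapause termination `z₂ = σ(α_d2(D_week − β_d2)) · σ(α_t2(Tw_week − β_t2))`,
  active only while days lengthen (δD > 0),

where `D_week`, `Ta_week`, `Tw_week` are trailing 7-day means of daylength,
air and water temperature and σ is the logistic function.  The larval
carrying capacity follows soil moisture,

```
K = κ_max (W / W*)^ν,
```

`W` being the water content of a single-bucket soil model (rain + snowmelt
in, Thornthwaite evapotranspiration and overflow out) and `W*` the
water-holding capacity; `ν = 0` fixes the capacity, `ν = 1` makes it
proportional to the soil-moisture ratio.  Daylength comes from the
standard solar-position calculation (sunrise zenith 90.833°), water
temperature from an equilibrium-relaxation energy balance.  The system is
integrated by classical RK4 with each day's environment held constant.

Weekly trap counts `n_w` are modelled as Poisson with mean
`λ_w = capture_rate × (weekly mean of A)` (default capture rate 1 %);
`κ_max` and the eight diapause parameters are fitted by a
simulated-annealing Metropolis search on the Poisson log-likelihood
(`κ_max` and slopes in log10 space).

## Worked example

Everything runs on seeded synthetic data — no downloads:

```python
import aedespop as ap

weather = ap.generate_weather(ap.WeatherGenConfig(seed=42), 4)      # 4 years, Tokyo-like
obs, truth = ap.generate_trap_counts(weather, ap.TrapGenConfig(seed=42))

model = ap.MosquitoPopulationModel(obs, weather, ap.TOKYO_SITE)
res = model.fit(config=ap.CalibrationConfig(n_levels=20, iters_per_level=100, seed=1))
print(res.summary())
```

```
Mosquito Population Model — annealing fit
=========================================================
No. observations:    156    Log-likelihood: -88.362
Capture rate:      0.010    Seed: 1
---------------------------------------------------------
parameter                     estimate    (log10 form)
---------------------------------------------------------
kappa_max                         1711         10^3.23
nu                                   1
alpha_d1 (per h)             3.553e+05         10^5.55
alpha_d2 (per h)                 559.1         10^2.75
alpha_t1 (per degC)          3.991e+05         10^5.60
alpha_t2 (per degC)              72.65         10^1.86
beta_d1 (h)                      14.46
beta_d2 (h)                      11.11
beta_t1 (degC)                   28.61
beta_t2 (degC)                   8.361
=========================================================
```

The fitted induction threshold `β_d1 ≈ 14.5 h` says egg-laying switches to
diapause eggs once the weekly daylength drops below about 14.5 h on the
shortening branch (mid-July at 35.7° N); `β_d2 ≈ 11.1 h` places diapause
break in early March; `κ_max ≈ 1711` is within 15 % of the generating
truth (2000).  Seasonal diagnostics:

```python
print(res.period_loglik())
# {(16, 23): -4.54, (29, 36): -14.04, (42, 49): -0.03}
s = ap.summarize(res.simulate(), burn_in_years=1)
print(s.peak, s.peak_week, s.onset_week, s.termination_week)
# peak 606.8 adults, peak week 29, season weeks 21–36
```

Scenario comparison uses the same objects: `ap.scenario_shift` warms or
re-scales a weather series, `ap.summarize` reduces a run to averaged
weekly dynamics, and `ap.compare_models` / `ap.compute_bias` form peak
ratios between model variants or climate inputs.

A command-line layer wraps the same functions:

```
aedespop synth --seed 3 --out-dir data/           # weather.csv, traps.csv, truth.yaml
aedespop calibrate --weather data/weather.csv --traps data/traps.csv \
                   --seed 1 --out fit.yaml
aedespop project --weather data/weather.csv --params fit.yaml --out proj/
```

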