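# chitalseason

Tools for analysing **reproductive seasonality in tropical deer
populations** from the three data streams a field programme typically
produces: antler-state observations (camera traps + incidental
sightings), cull records of females with foetal masses, and monthly
rainfall totals.

The scientific question the package addresses: are male breeding
condition (hard antler) and female conceptions seasonal, what drives
them (photoperiod vs lagged rainfall), and are the two sexes' seasonal
peaks synchronised?  In aseasonal-photoperiod environments — e.g. chital
(*Axis axis*) introduced to tropical Australia — the sexes can drift
apart, and quantifying that asynchrony requires an end-to-end pipeline:

1. **Foetal-age back-calculation** (`growth`).  Foetal mass *Y* (g) maps
   to age *t* (days) through a piecewise growth curve: exponential below
   the 560 g phase boundary, *t* = ln(*Y*/*a*₀)/*k* with
   *a*₀ = 1.3196 g, *k* = 0.0504 d⁻¹; linear above it,
   *t* = (*Y* + 2832.25)/27.95 (sign-corrected so that age at the
   3690 g birth mass is consistent with the 229-day gestation; the raw
   published sign convention is available behind a flag).  Conception
   date = cull date − *t*.
2. **Monthly aggregation** (`aggregate`).  Camera triggers < 60 min
   apart at one camera are collapsed to independent detections; antler
   states pool into monthly hard-antler proportions; conceptions pool
   over an *at-risk* denominator — the culled females whose gestation
   window covers each month.
3. **Cosinor regression** (`cosinor`).
   *y*ₜ = β₀ + β₁ sin(2π*t*/12) + β₂ cos(2π*t*/12) + εₜ.
   Amplitude √(β₁²+β₂²) is the seasonality effect size; the acrophase
   atan2(β₁, β₂) gives the peak month; a joint F-test on (β₁, β₂)
   decides seasonality.
4. **Poisson rate models + AICc model averaging** (`glmselect`).
   Monthly counts with log-exposure offsets, candidate terms
   {daylength, rainfall at lags 0/1/3/6 (cumulative or single-month),
   year, interactions, male hard-antler proportion}, at most one
   rainfall lag per model; models within ΔAICc < 2 of the best are
   combined by full (zero-substitution) averaging with unconditional
   standard errors.
5. **Asynchrony** (`pipeline`).  The signed circular displacement
   between the male and female peak months.

A synthetic-data generator (`simulate`) plants known truth — seasonal
gamma/Dirichlet rainfall (689 mm yr⁻¹, CV 47%, 75% in Nov–Mar), a
sinusoidal hard-antler probability, and a rainfall-lagged conception
hazard with gestation-window truncation — so every stage can be
validated by parameter recovery.

The statistical cores are scikit-learn-style estimators
(`CosinorRegressor`, `PoissonGLM`) and compose with sklearn tooling;
the module-level functions (`fit_cosinor`, `fit_poisson_glm`, …) are
thin wrappers.

## Worked example

```python
from chitalseason import *

truth = SimulationTruth(seed=1)          # planted: antler peak month 6,
data  = generate_dataset(truth)          # lag-3 rain effect 0.004 per mm
obs, rain = data["observations"], data["rainfall"]
culls = data["culls"].drop(columns=["true_conception_date"])

config = AnalysisConfig()
male_monthly = monthly_hard_antler(dedupe_camera_triggers(obs))
covs = build_covariate_table(rain, [m for m in male_monthly.index
                                    if (m - 6) in rain.index])
male = run_male_analysis(obs, covs, config)

at_risk = at_risk_denominator(culls["cull_date"], config.detection_window_days)
covs_f = build_covariate_table(rain, [m for m in at_risk.index
                                      if (m - 6) in rain.index])
female = run_female_analysis(culls, covs_f, config, male_monthly=male.monthly)

print(male.cosinor.peak_month, female.cosinor.peak_month)
print(asynchrony(male.cosinor, female.cosinor).months)
print(female.averaged.estimates.round(4))
```

prints (seed 1):

```
male   peak 6.02   amplitude 0.257   p_joint 1.2e-42
female peak 2.79   amplitude 0.072   p_joint 3.3e-06
asynchrony 3.23 months
             estimate  se_unconditional  z_value  ci_low  ci_high
Intercept     -3.4817            1.0075   3.4558 -5.4563  -1.5070
rain_lag3      0.0045            0.0006   8.1412  0.0034   0.0056
prop_hard      0.2009            0.4142   0.4852 -0.6108   1.0127
daylength_h   -0.0292            0.0782   0.3734 -0.1824   0.1240
```

The planted antler peak (month 6) is recovered at 6.02; the planted
lag-3 rainfall effect (0.004 mm⁻¹) is estimated at 0.0045 with a tight
CI and tops the AICc ranking; the male–female displacement of 3.2
months reflects the construction (antler peak mid-year, conceptions
following the rain).

The same pipeline runs from the shell:

```sh
chitalseason simulate --seed 1 --out simdata
chitalseason report --observations simdata/observations.csv \
    --culls simdata/culls.csv --rainfall simdata/rainfall.csv --out results
```

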