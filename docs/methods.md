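# Methods

## Foetal growth model and back-calculation

Foetal age is obtained by inverting a two-phase growth curve for chital:
exponential growth up to the 560 g boundary, linear growth from there to
the 3690 g birth mass, with a 229-day gestation.

* Exponential inverse: `age = ln(mass / a0) / k`, `a0 = 1.3196` g,
  `k = 0.0504` d⁻¹.  The day-1 mass also circulates as 1.1396 g — a
  probable digit transposition; the value inside the operative equation
  (1.3196) is the default, and `a0` is configurable.
* Linear inverse: the published form `(Y − 2832.25)/27.95` evaluates to
  ~31 days at birth mass, inconsistent with a 229-day gestation.  The
  sign-corrected `(Y + 2832.25)/27.95` gives 233.4 d at 3690 g and
  121.4 d at 560 g, consistent with both anchors, and is the default.
  `intercept_sign="printed"` restores the published form (with a
  warning) for comparison.
* Exactly 560 g is assigned to the exponential branch, so the phase
  boundary evaluates to 120.05 d, matching the stated ~120-day
  exponential phase.  The two branches disagree by 1.3 d at the
  boundary — an artefact of the rounded published constants — so the
  inverse has a small upward jump there and the forward model
  (`mass_from_age`, needed by the simulator) a corresponding
  discontinuity.  `mass_from_age` is the exact right-inverse:
  mass → age → mass round-trips to 1e−9 relative everywhere.
* Because the corrected linear form reaches 233.4 d at birth mass, ages
  up to `max_age` (233.4 d) are treated as valid, slightly beyond the
  nominal gestation.  The residual reflects rounding in the published
  slope/intercept, not a biological claim.
* Ages are rounded half-away-from-zero to whole days before calendar
  subtraction, so conception dates are whole dates.  A measured mass
  below the curve's one-day mass (~1.39 g; possible under measurement
  noise) would invert to a negative age and is floored to 1 day — the
  detection limit.  No error model is propagated through the inverse:
  foetal-mass uncertainty is a recognised non-goal.

## Aggregation

* **Camera deduplication.**  "Independent detection" is implemented as
  greedy per-camera thinning: a trigger is kept iff it falls at least 60
  minutes (configurable) after the last *kept* trigger at that camera.
  Greedy thinning is the common camera-trap convention and is
  idempotent.  A gap of exactly the window length is kept; incidental
  observations are never thinned.
* **Monthly antler counts.**  Uncertain/unknown antler states are
  excluded from numerator and denominator alike.  Months with no usable
  records inside the observed span are reported as missing (NaN), never
  zero, and are dropped from model fits rather than imputed.
* **At-risk denominator.**  Every culled female — pregnant or not —
  counts toward each month intersecting her detectability window, the
  half-open interval `(cull − W, cull]`: a conception is detectable at
  cull only if it occurred within one gestation beforehand.  Months are
  counted whole (no fractional weighting); month-level granularity
  matches the analysis binning.  The pipeline uses
  `W = ceil(max_age) = 234` d rather than the nominal 229 d, because
  back-calculated ages can legitimately reach the curve's own maximum
  and every datable conception must lie inside its female's window.
  Whether only breeding-age females should enter the denominator is an
  open design question; all culled females are counted by default and
  the operation accepts any cull subset.

## Cosinor regression

Monthly proportions are regressed by OLS on
`[1, sin(2πt/12), cos(2πt/12)]` with `t` the month-of-year (Jan = 1);
multiple years pool with each year-month as one observation.  Both
harmonic terms are always fitted — a sine-only model cannot represent
arbitrary phase; the sine-term t-test is reported for comparability
with conventional "sinw" tables, while the phase-invariant joint F-test
is the headline seasonality decision (α = 0.05 default).  Amplitude and
acrophase derive from the coefficients; the peak month is continuous on
[1, 13).  Fits require ≥ 4 non-missing months spanning at least half a
period.  A numerically constant series returns amplitude 0 with p = 1
rather than a 0/0 statistic.  Weighted fits (e.g. by monthly sample
size) are supported but off by default.  Residuals are treated as
independent Gaussian; autocorrelation-robust errors and multi-harmonic
fits are out of scope.

## Poisson rate models and model averaging

Counts with log-exposure offsets are fitted by iteratively reweighted
least squares (log link, convergence when the relative deviance change
is < 1e−8, max 100 iterations, linear predictor clipped at ±30 against
separation blow-up); standard errors come from the inverse Fisher
information.  Model quality is AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) — the
small-sample correction is material at monthly n.

Candidate sets are all additive subsets subject to: at most one
rainfall-lag term per model (the lags measure one quantity at different
windows); interactions only with both mains present; mutually exclusive
groups (daylength vs temperature, which are far too collinear to fit
together) never co-occurring.  Year enters as a categorical factor by
default (configurable to numeric).

Averaging over the ΔAICc < 2 top set uses the **full (zero
substitution)** convention: `β̄ = Σ wᵢ βᵢ` with `βᵢ = 0` where the term
is absent, and unconditional variance `Σ wᵢ (varᵢ + (βᵢ − β̄)²)`.
Akaike weights are computed over the whole candidate set for the model
table and renormalised within the top set for averaging (toggleable).
Confidence intervals are normal-theory `β̄ ± 1.96·SE`.  Overdispersion
handling (quasi-Poisson/negative binomial) is out of scope.

## Covariates

Rainfall lags support two conventions: **cumulative** (default) sums
months `m−L … m` inclusive; **single** takes the single month `m−L`.
The convention is recorded in the output table's metadata.  Missing
rainfall months raise with the gap named — a silent zero would
masquerade as drought.  Daylength defaults to the astronomical mean day
length for the month (solar declination + hour angle) at a configurable
latitude (default 20.08°S, the study region); a user-supplied 12-value
monthly table takes precedence, and polar latitudes are rejected.
Temperature or other monthly covariates pass through as extra columns.

## Synthetic data

The generator emulates the study conditions so recovery tests are
well-posed; it is not a mechanistic deer model.

* **Rainfall**: yearly totals Gamma(mean 689 mm, CV 0.47), apportioned
  to months by a Dirichlet whose expectation puts 75% of rain in
  Nov–Mar (total concentration 30 — enough spread that wet seasons
  shift between years, as observed).
* **Antler states**: per month a fixed number of records
  (default 200) that are hard with probability
  `clip(0.6 + 0.25·cos(2π(m − 6)/12), 0, 1)`; 30% arrive via one of 20
  cameras, a quarter of those in bursts of 1–2 extra triggers < 60 min
  later to exercise deduplication.
* **Culls**: 30 females on each of eight occasions mirroring the field
  calendar (Oct 2014 – Mar 2018).  Within a female's gestation window,
  conception intensity is proportional to
  `exp(rain_effect · lagged rain)` (default lag 3 cumulative,
  0.004 mm⁻¹); her probability of being pregnant at cull is the
  complement of monthly base-rate hazards (0.12 per female-month at
  average rainfall), which puts monthly conception percentages in the
  observed 5–20% band.  Foetal mass is the forward growth curve times
  lognormal noise (σ = 0.1), capped at birth mass.  The
  gestation-window truncation is applied at generation: conceptions
  outside one gestation before a cull are unobservable, so
  edge-of-window months are under-counted exactly as in the real
  observational process.
* Defaults for quantities no study reports (rain effect size, mass
  noise, base rate) were chosen once for recovery-test power, not
  biological realism, and are all configurable.  Everything derives
  from one integer seed; a fixed seed reproduces datasets bit for bit.

What passing recovery tests show: the pipeline correctly inverts data
generated by its own model family at field-realistic sample sizes.
What they do not show: robustness to overdispersion, observer bias,
non-log-linear rainfall responses, individual heterogeneity, or spatial
structure — none of which the generator emulates.

## Problem sizes

The replicated checks use 2000 null series of 48 months for the
seasonality type-I-error calibration, 100 end-to-end synthetic studies
for peak-recovery and lag-selection rates (test suite; the acceptance
script uses 20), and 200–500 simulated fits for GLM parameter-recovery
checks — sizes at which Monte-Carlo error is small relative to the
tolerances being asserted.

## Known limitations

* The cosinor treats months as equally informative regardless of
  sample size unless weights are supplied.
* Model-averaged CIs are normal-theory; small top sets with unstable
  fits can make them optimistic.
* The at-risk denominator counts all culled females; if a cull includes
  juveniles, conception percentages are diluted.
* The growth curve is taken as fixed and error-free; foetal-mass
  measurement error propagates directly into conception-date error
  (~2 d in the exponential phase, up to ~10 d late in gestation at 10%
  mass error).
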