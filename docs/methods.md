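# Methods

This note documents the models and procedures implemented in `miniheat`,
the parameters that matter, the synthetic data the test-suite runs on, and
the numerical and design choices made where more than one reasonable option
existed.

## Mini-heatwave detection

A mini-heatwave is a continuous period during which indoor air temperature
meets or exceeds a threshold for at least a minimum duration.  Given
validated samples (tᵢ, Tᵢ) the detector applies, in order:

1. **Threshold flagging** — candidate where Tᵢ ≥ θ.  The comparison is
   inclusive so a plateau exactly at θ counts as an event.
2. **Onset inclusion** — points whose forward-difference slope
   (Tᵢ₊₁ − Tᵢ)/(tᵢ₊₁ − tᵢ) exceeds the inclusion rate join the candidate
   set even below θ.  Slopes are per minute of *actual elapsed time*, so
   data gaps do not fabricate steep slopes.
3. **Cooling exclusion** — points with slope at or below the exclusion rate
   are removed, as are below-threshold points inside a *sustained cooling
   run*: a maximal monotone non-increasing stretch lasting at least
   `cooling_run` minutes.
4. **Gap handling** — surviving candidates are grouped; a new event starts
   whenever consecutive candidates are more than `min_gap` minutes apart.
   One rule serves both purposes: sub-`min_gap` dips are merged and longer
   data gaps split events, so events are never extrapolated over missing
   data.
5. **Duration filter** — events shorter than `min_duration` are discarded.

Events use a right-open interval: `end` is the last included sample plus one
nominal sample step (the median inter-sample spacing), so an n-sample
plateau at 1-min resolution has duration n minutes and `duration = end −
start` holds exactly.  Event peak and mean temperatures are computed over
all samples inside [start, end), including any merged dip.

Parameter defaults: θ = 26 °C (the English Heatwave Plan indoor safety
limit), minimum duration 10 min, inclusion slope +2 °C min⁻¹, exclusion
slope −2 °C min⁻¹, merge gap 30 min, cooling run 10 min.  The ±2 °C min⁻¹
rates are very steep for indoor air and in practice fire only on sensor
artefacts or abrupt local heat sources; they are configuration defaults,
not hard-coded.  The merge gap and cooling-run length have no canonical
values; 30 min is small relative to the multi-hour events the detector
finds, and both are exposed in `DetectorConfig`.

The production implementation is vectorized; the test-suite holds it
identical, event-for-event, to a literal per-point re-implementation of the
five steps on thousands of random-walk series.

**Outdoor rule.**  A heatwave is at least `min_days` (3) consecutive
calendar days — local-midnight boundaries, a missing day breaks the run —
whose daily maximum temperature reaches or exceeds the regional threshold
(28 °C default, London).  Verified exhaustively against run-length
enumeration over all week-long hot/cool patterns.

## Heat index and risk categories

The heat index is the nine-term Rothfusz regression evaluated in its native
°F scale and converted to °C afterwards; category boundaries, not the
formula, are converted.  The polynomial is applied to **all** readings,
including below 80 °F where the NWS intends a simpler formula — that usage
follows the study design this package supports; an opt-in low-temperature
fallback (`low_temp_fallback=True`) implements the NWS simple average
formula for users who want it.

Categories follow the NWS bands converted to °C at one-decimal rounding:
< 26.7 comfortable, 26.7–32.2 caution, 32.2–39.4 extreme caution, 39.4–51.1
danger, ≥ 51.1 extreme danger.  Binning is half-open with each cut point in
the upper category.  The fifth boundary is 51.1 °C, the Celsius conversion
of the NWS 124 °F cut (this table is occasionally misprinted with the 124
left in °C; the Fahrenheit origin is authoritative here).

Against the published chart grid (TF 80–110 °F × RH 40–100 %, step 5) the
implementation agrees within the 1.3 °F fit error the NWS states for the
regression; the printed chart equals the raw polynomial rounded to whole
degrees, so the observed maximum deviation is 0.5 °F.

## Psychrometrics and the comfort zone

Saturation vapour pressure over liquid water uses the Hyland–Wexler
formulation (≈ 2339 Pa at 20 °C, ≈ 101325 Pa at 100 °C).  Humidity ratio is
W = 0.621945·p_v/(P − p_v) with p_v = RH/100·p_ws(T); total pressure
defaults to 101325 Pa.  Specific enthalpy is h = 1.006·T + W·(2501 +
1.86·T) kJ per kg dry air, zero at the 0 °C dry-air reference.

Comfort-zone membership is a point-in-polygon test in (dry-bulb, W)
coordinates, boundary-inclusive.  The shipped polygon approximates the
ASHRAE-55 graphical summer (0.5 clo) zone at an indoor air speed of
0.1 m s⁻¹: dry-bulb roughly 23–27 °C, humidity ratio capped at
0.012 kg kg⁻¹, lower humidity bound near a 2.8 °C dew point, with the warm
edge slanting so drier air tolerates slightly warmer temperatures.  ASHRAE
defines the zone graphically rather than as published vertices, so any
vertex list is an approximation; the polygon is data, overridable per call.

## Regression models

Pooled OLS of 5-min-averaged indoor temperature on outdoor temperature,
building attributes and socio-economic indicators, with household features
broadcast over time rows.  Encodings: EPC band B/C/D/E → 0/1/2/3 (0 most
efficient); self-rated condition 0 (worst, urgent repair) → 3 (best); IMD
group passed through as an ordinal; tenure → four dummies against
"homeowner with mortgage"; house type → two dummies against "flat/apartment
(high-rise on a low floor, or low-rise)".  The five standard
specifications nest: base (outdoor + condition + EPC + IMD), +house type,
+tenure, all, and all + 6-h lagged outdoor temperature (72 steps at 5-min
resolution; rows lacking lag history are dropped, never imputed).

Inference is classical homoskedastic OLS with two-sided t-tests and a fixed
significance threshold of p < 0.01; no multiple-testing correction.
Because observations within a household-day are strongly autocorrelated,
these standard errors are optimistic — clustered or HAC errors would be the
robust choice and are deliberately out of scope, matching the plain-OLS
design the package mirrors.  Rank deficiency (e.g. a tenure level absent
from a small cohort) is reported as an error naming the offending columns
via pivoted QR, never silently "fixed".  A constant response reports
R² = 0 rather than NaN.

## Synthetic study generator

The generator defines the conditions every test runs under.

**Outdoor** (5-min): T(t) = mean + amplitude·sin(diurnal, peak 15:00) +
episode boost + AR(1) noise.  Defaults: mean 21 °C, amplitude 5 °C,
stationary noise sd 1 °C with persistence φ = 0.98 per 5-min step, and two
embedded episodes (days 20–22, +4 °C; days 33–40, +6 °C) whose boosts push
daily maxima past the 28 °C outdoor threshold — yielding one 3-day and one
8-day heatwave over a 43-day run starting 2 August, the span of a typical
single-summer deployment.

**Cohort**: 39 households by default, attributes drawn from fixed
frequencies representative of a deprived-borough sample (EPC B/C/D/E =
12/9/8/4; IMD more/less deprived = 16/23; five tenure and three house-type
levels; four condition levels).  `balanced_profiles` provides a
deterministic cohort covering every categorical level, used where
full-rank designs are a precondition rather than a finding.

**Indoor** (1-min): first-order lumped-capacitance response
T_in′ = (T_eq − T_in)/τ with equilibrium T_eq = a₀ + g·T_out + covariate
offsets, per-household τ drawn uniformly from 2–8 h, plus iid measurement
noise (sd 0.1 °C).  The discrete update uses the exact exponential
integrator k = 1 − e^(−Δt/τ) — exact for piecewise-constant forcing — so
the step response matches 1 − e^(−t/τ) at sample times to machine
precision rather than the ~1 % error a forward-Euler step would leave at
τ = 30 min.  Defaults a₀ = 11.2 °C and g = 0.45, with covariate
coefficients making better-condition, less-deprived homes warmer, were
chosen once so the default cohort shows the phenomenology the detector is
built for: roughly two-thirds of households affected, a handful of
multi-hour events each, onsets peaking mid-afternoon, and excursions
concentrated in (and lagging behind) the outdoor episodes.  RH is an
independent bounded diurnal signal peaking pre-dawn — sufficient for
exercising the comfort module; humidity–temperature coupling is not
modelled.

A second, purely linear generator produces 5-min indoor series directly
from the pooled regression equation with chosen gains (defaults 0.22, or
0.16 current + 0.13 lagged), for parameter-recovery testing where the
estimand must equal a generating coefficient exactly.

**What passing tests do and do not show.**  The generator has no solar
gain, occupant behaviour, ventilation events, or humidity–temperature
coupling, and its AR(1) weather is far tamer than real synoptic
variability.  Green tests demonstrate that the algorithms are implemented
correctly and behave as specified on data with known structure — not that
detected event counts or fitted coefficients on real deployments will
match any particular study's values.

## Conventions and degenerate inputs

- Resampling bins are left-closed right-open, labelled by the left edge;
  empty bins are emitted as missing.  No imputation anywhere.
- Duplicate timestamps keep the first record; unordered files are sorted
  with a warning.  Temperature outside −10…60 °C (configurable) and RH
  outside 0–100 % are dropped and counted.
- Timestamps are naive local clock time; DST transitions are the user's
  responsibility.
- Analysis windows are half-open [start, end); midnight belongs to the day
  it starts.
- Event-count statistics (means, medians, stratified means) are over
  *affected* households by default, switchable to all households.

## Problem sizes

The default test-suite and the acceptance script run the full 39-household
× 43-day study (≈ 2.4 M indoor samples), 1,000 oracle-comparison series of
up to 2,000 points, and regression recoveries on ≈ 480,000 rows; the whole
suite completes in well under a minute on one core.
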