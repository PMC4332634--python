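# Methods

## The problem and the modelling idea

Daily fire-danger rating asks: given today's weather (and the weather
history encoded in drought and moisture indices), how suitable is today for
a fire ignition? `fireniche` treats this as a *temporal niche* problem. For
a given fire regime — a set of calendar months, an ignition cause and a
year period — every day of the regime is a point in an environmental space
spanned by meteorological variables and fire-weather indices. Days with at
least one ignition ("fire days") are presence samples; **all** in-regime
days, fire days included, are the background. A presence-background model
then scores each day, and the score is the fire-danger index.

Two model families are implemented:

- **Maxent**: the Gibbs distribution `q_λ(x) = exp(λ·f(x)) / Z(λ)` over the
  background that maximises the L1-penalised mean presence log-likelihood
  `mean_pres[λ·f] − log Z(λ) − Σ_j β_j |λ_j|`. At the optimum the KKT
  conditions confine each feature's expectation under `q_λ` to within
  `β_j` of its presence-sample mean.
- **Logistic GLM**: ordinary maximum-likelihood logistic regression of the
  fire-day indicator (fire day = 1, all other days = 0) on the raw
  variables.

Because presences belong to the background, even a perfect score function
ties each presence against its own copy among the background days, so the
presence-vs-background AUC (written AUC.bg) is capped at `1 − p/2` for
prevalence `p` = fire days / background days. All model comparison is done
in AUC.bg units against this ceiling.

## Derived weather variables

From daily mean temperature `T` (°C) and relative humidity `H` (%):

- saturation vapour pressure `es(T) = 0.6108·exp(17.27·T/(T+237.3))` kPa
  (Magnus form, constants a = 17.27, b = 237.3 °C);
- `VPD = es(T)·(1 − H/100)`; dew point by inverting the Magnus form.

Rain-history variables use a configurable rain-day threshold, default
0.2 mm (typical gauge resolution): `WeekRain` sums precipitation over the
7 days strictly before the current day (window configurable to include the
current day), `DaysSinceRain` counts days since the last rain day (0 on a
rain day), `LastRainSum` totals the most recent maximal run of consecutive
rain days. Days whose trailing window or rain history is incomplete carry
NaN and a `burn_in` flag; downstream dataset assembly drops flagged days
rather than imputing weather.

## Fire-weather indices

Fifteen indices are computed from the canonical published formulations.
The Canadian FWI system (FFMC, DMC, DC → ISI, BUI, FWI) uses the standard
recursions with the 46–50°N monthly day-length factors, start-up codes
(85, 6, 15) — configurable, as the conventional default — and internal
m/s → km/h conversion. Indices are computed year-round; snow cover enters
the models as a variable and does not suspend index computation, and DC
overwintering is not applied. One deliberate deviation from a literal
reading of the Nesterov accumulator: the daily increment `T·(T − Tdew)` is
floored at zero so that sub-zero days (where the product can turn negative)
do not make a drought accumulator decrease during a rain-free spell; the
index still resets on days with more than 3 mm of rain.

Site-dependent indices: KBDI uses the SI formulation (water deficit
0–203.2 mm, 5.1 mm per-wet-run rain threshold, drying driven by the
station's mean annual precipitation; the daily mean temperature is used,
matching the available input). The McArthur Mark 5 FFDI takes its drought
factor from KBDI, days-since-rain and the last rain event (events under
2 mm ignored, factor capped at 10). The Baumgartner index is the sum of
(potential evapotranspiration − precipitation) over the five days
preceding the current day (lag exposed as a parameter), with PET from the
FAO-56 Penman–Monteith reduced-data variant (solar radiation from the
diurnal temperature range, actual vapour pressure from Tmin) — chosen
because the index's stated inputs (Tmax/Tmin, wind, elevation, latitude)
match exactly that variant's requirements. The Orieux index runs a
Thornthwaite water budget on a 150 mm reservoir (evaporation scaled by
reserve/150, monthly PET from the site's mean monthly temperatures with
day-length correction) and reports both the continuous reserve and a
4-class danger scale (1: reserve > 100 mm; 2: 50–100 mm; 3: ≤ 50 mm and
wind ≤ 40 km/h; 4: ≤ 50 mm and wind > 40 km/h); the class is the model
variable. Munger's index is `0.5·n²` over consecutive days with less than
1.27 mm (0.05 in) of rain; Fosberg's FFWI uses the three-branch
equilibrium moisture content in °F/mph units internally.

Stateful indices carry an explicit `IndexState`; recomputing a series from
any checkpointed state reproduces the downstream values exactly, which the
tests exercise. The FWI implementation is cross-checked against an
independent scalar transcription of the published recursions and against
the classic start-up worked example (April, T = 17 °C, H = 42%, wind
25 km/h, no rain → FFMC 87.7, DMC 8.5, DC 19.0, ISI 10.9, BUI 8.5,
FWI 10.1). One numerical caveat: the published FFMC code↔moisture
conversion pair is not an exact inverse (147.2·101 vs 59.5·250), so a
"no-change" day can move the code by up to ~0.05; tests tolerate exactly
that.

## Regimes and datasets

Default regimes: winter `w` (December–April), summer anthropogenic `sa`
and summer natural `sn` (May–November). Background membership is by
calendar month within the period's years — December of the final year is
included even though its season runs into the following year; this
convention reproduces the period day counts exactly (e.g. 3,328 winter
days over 1991–2012, including six leap Februaries). Several same-day
events collapse to one fire day; events outside the regime's months or
period are excluded with a warning and counted. Prevalence is reported at
3 decimals; internal arithmetic keeps full precision.

## Maxent implementation choices

The implementation emulates, rather than bit-reproduces, the defaults of
the original Maxent software, since rank-based AUC.bg is invariant to
monotone rescalings and robust to implementation-level differences:

- **Features.** Variables are min-max rescaled over the training
  background so every feature maps into [0, 1]. Classes: linear,
  quadratic, product (all pairs), hinge (both directions) and threshold;
  hinge/threshold knots at background quantiles, 50 per variable per
  direction by default (a parameter, since the original default knot count
  is not documented precisely). Auto-selection by presence count m:
  linear for m < 10, +quadratic from 10, +hinge from 15,
  +product/threshold from 80. Binary variables (snow cover) enter as their
  indicator only.
- **Regularisation.** `β_j = multiplier · r_class(m) · s_j / √m`, with
  `r_class` the published per-class tuning tables (piecewise-linear in m,
  clamped at the ends) and `s_j` the presence-sample SD of the feature,
  floored (0.05 for hinge/threshold, 1e-3 otherwise) so near-constant
  features are not penalty-free.
- **Optimiser.** The penalised objective is convex; it is minimised by
  proximal gradient with FISTA momentum, backtracking line search and an
  objective-increase restart, starting from λ = 0 (the uniform
  distribution, which also makes fitting deterministic). Convergence when
  the penalised objective changes by less than 1e-5 between iterations,
  cap 500 iterations — mirroring the original defaults. The contract is
  the KKT box condition at tolerance 1e-3, which the tests check directly,
  plus equivalence with brute-force grid search on 1-feature problems.
- **Scoring.** Raw output `q_λ` sums to 1 over the training background;
  the logistic output `q·e^H/(1+q·e^H)` (H = entropy of `q_λ`) is also
  available. Out-of-range values at scoring time are clamped to the
  training bounds. All evaluation is rank-based, so the choice of output
  scale is irrelevant to AUC.bg.

The logistic baseline delegates to statsmodels' `Logit`; complete
separation (flagged by the optimiser or absurd coefficient magnitudes)
falls back to a tiny-ridge fit (scikit-learn, L2 with C = 1e4) and the
model is marked `separation_fallback`.

## Selection and evaluation

- **Spearman filter.** Candidate subsets must have all pairwise |ρ_S|
  strictly below 0.9, computed on the regime's full background (the filter
  concerns environmental redundancy, not presence-conditional structure —
  an interpretation, exposed via parameters). Enumeration is exhaustive
  over the requested size range (default 2–10), with a budget cap that
  falls back to the smallest subsets first.
- **Pools.** `meteo` (11 station/derived variables), `indices` (the 15
  indices), `mixed` (meteo minus VPD, LastRainSum and DaysSinceRain, plus
  all indices — the composition used in the motivating analysis, exposed
  as configuration).
- **Folds.** Consecutive, non-overlapping blocks of two whole calendar
  years; the period must divide evenly. For winter datasets December is
  attached to the following winter's fold (Dec 2002 evaluates with
  Jan–Apr 2003); December of the final year stays in the last fold. A
  `calendar` policy is available as an alternative.
- **AUC.bg** is the Mann-Whitney rank estimate with half-credit for ties,
  computed presence-vs-whole-background; it equals brute-force pair
  counting (property-tested) and attains `1 − p/2` exactly under perfect
  separation.
- **Cross-validation** fits on the training years and scores the test
  block against its own background. Folds with no test presence cannot
  define an AUC and are excluded from the mean with a warning (a policy
  decision; relevant at low prevalence).
- **Wilcoxon comparison.** Two-sided signed-rank on per-fold AUC.bg
  differences, Pratt handling of zeros (zeros ranked, then dropped from
  the statistic), exact null by convolution over sign assignments for up
  to 25 non-zero differences (half-integer midranks handled on a doubled
  lattice), normal approximation with tie/zero variance corrections
  beyond. Significance classes: *** p < 0.001, ** p < 0.01, * p < 0.05,
  else ns. No multiple-testing correction is applied across comparison
  matrices.
- **Best-model criterion.** Mean test AUC.bg; ties break toward fewer
  variables, then lexicographically, making the ranking invariant to pool
  ordering. Selecting on test performance is optimistic; the ranking is a
  selection device, not an unbiased performance estimate.

## Synthetic data

The generator emulates a single valley station with an Insubrian climate:

- temperature: annual harmonic (mean 12 °C, amplitude 9 °C, warmest near
  day 200) plus an AR(1) anomaly (φ = 0.7, innovation SD 1.8 °C); diurnal
  range ~8 °C split randomly around the mean;
- rain: two-state Markov chain (p_wet|dry = 0.22, p_wet|wet = 0.52,
  ±0.10 seasonal modulation peaking in summer), gamma wet-day amounts
  (shape 0.8, scale 16 mm) — about 1,800 mm/year concentrated in summer;
- humidity: dry-day base 62% with seasonal swing, +22 points on wet days,
  clamped to [5, 100]; foehn episodes (Poisson, ~10/year, mean 2 days)
  multiply humidity by 0.45 and add 2.5 m/s of wind on dry days;
- cloud cover tracks rain and humidity; snow cover switches on after
  sub-zero precipitation and off above +2 °C.

Ignitions are conditionally independent across days given weather: each
in-regime day is a fire day with probability
`logistic(a + Σ c_v · z_v)` over standardised variables, with the
intercept `a` calibrated by bisection so the expected prevalence matches a
target. There is no fire-spread persistence, no multi-station structure,
no human-behaviour effects (bans, weekends) and no reporting error — so
passing the recovery tests shows the pipeline can find a weather signal
that is really there, not that real fire data behaves this simply.

## Problem sizes used in the test suite

The end-to-end recovery experiment uses 22 synthetic years, a 3-variable
ignition rule (per-SD coefficients 1.0 on VPD, 0.7 on days-since-rain,
0.5 on wind) at target prevalence 0.1 over the May–November regime,
20 seeds, a 6-variable meteorological pool searched at subset size 2 with
linear+quadratic features, and 11 two-year folds — sizes chosen so the
whole suite runs comfortably on a single CPU while keeping every
distributional property testable. The FWI oracle comparison runs over a
2-year synthetic series.

## Known limitations

- The Maxent emulation will not reproduce the original Java
  implementation's coefficients bit-for-bit (different optimiser, knot
  placement at quantiles rather than even spacing); agreement is at the
  level of the fitted distribution's constraints (KKT boxes) and of
  rank-based evaluation.
- Index formulations with genuinely ambiguous published variants
  (Baumgartner's PET, Orieux's danger classes, Nesterov's cold-day
  handling) follow the documented choices above; all are parameterised or
  isolated in single functions.
- Backgrounds use one station; no spatial heterogeneity.
- The subset search cost grows combinatorially; the budget cap trades
  completeness for time and flags itself in the log when it bites.
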