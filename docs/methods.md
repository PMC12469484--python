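# Methods

## Heat index

The heat index is the Rothfusz nine-term regression in °F,

HI = −42.379 + 2.04901523·T + 10.14333127·R − 0.22475541·T·R
   − 0.00683783·T² − 0.05481717·R² + 0.00122874·T²·R
   + 0.00085282·T·R² − 0.00000199·T²·R²,

with T the daily maximum temperature and R the daily minimum relative
humidity (paired because RH typically bottoms out at the thermal
peak).  Branching: below 80 °F a simplified formula
0.5·(T + 61 + 1.2·(T − 68) + 0.094·R) is used, falling back to the
full regression whenever the simplified value exceeds 80 °F.  A dry
adjustment ((13 − R)/4)·√((17 − |T − 95|)/17) is subtracted when
R < 13 % and 80 ≤ T ≤ 120 °F, and a humid adjustment
((R − 85)/10)·((87 − T)/5) is added when R > 85 % and 80 ≤ T ≤ 87 °F.
Two numerical conventions worth noting:

* the dry-adjustment radicand crosses zero at T = 112 °F; the term
  vanishes smoothly there and is held at zero through the rest of the
  stated region rather than producing a complex value;
* the fallback from the simplified formula goes directly to the full
  regression (no temperature-averaging preliminary step); the
  difference is confined to a narrow band around 80 °F.

All public I/O is °C; conversions are lossless double precision.

## Climatology and detection

The threshold for day-of-year *d* is the empirical *p*-quantile
(default p = 0.90, linear interpolation between order statistics) of
all reference values whose day-of-year lies within a centered
`window_days` window (default 7) of *d*, wrapped across the year
boundary and pooled over all reference years (default 1991–2020,
minimum two full years).  Feb 29 sits at fractional position 59.5 so
its values join neighbouring windows; its own threshold is the mean of
the Feb 28 and Mar 1 thresholds.  A heatwave is a maximal run of at
least `min_duration` (default 3) consecutive calendar days with the
index strictly above threshold; a missing value or a calendar gap
breaks the run — no bridging, because "consecutive" is taken
literally.  Days with missing RHMIN propagate a missing HI; the
pipeline exposes a gap policy (`drop`, the default, or `interpolate`)
instead of silently guessing.

## Event statistics

For an event with daily excesses e₁…e_D above threshold: I̅ = mean,
I_max = max (ties to the earliest day), Ivar = population (1/D)
variance — the statistic describes the realised event, not a sample
estimate — and I_cum is stored as D·I̅ so the identity I_cum = D·I̅
holds exactly in floating point (it agrees with the naive sum to one
ulp).  Onset and decline rates divide I_max by the number of event
days strictly before/after the peak, floored at 1 so that an event
peaking on its first or last day has a finite rate equal to I_max.
All intensities are excesses over the day-of-year threshold; absolute
temperatures are recoverable from the raw series.

The daily exposure series is the within-event running cumulative
excess (zero outside events).  Its value on the last event day equals
the event's I_cum, and lagging it 1–7 days gives the delayed-exposure
design; only a daily series supports that lag structure, which is why
the event-level I_cum is "daily-ised" this way.

## LASSO selection

Predictors are standardised to zero mean and unit variance
(standardisation is refit inside each CV fold), the response is
centered, and the objective ‖y − Xβ‖² + λ‖β‖₁ is solved by
coordinate descent (sklearn) along a 100-point log grid from λ_max
(the smallest penalty that zeroes every coefficient,
2·max_j |x_jᵀ(y − ȳ)|) down to λ_max·10⁻⁴.  At λ = 0 the objective
*is* ordinary least squares and is solved as such.  λ is chosen by
10-fold CV; the default rule is the CV-error minimum, with a
one-standard-error rule available (`rule="1se"`) for conservative
selection — on pure-noise designs the minimum rule retains a few
spurious predictors in roughly a quarter of runs, while the 1-SE rule
returns the empty model essentially always.  A Gaussian squared-error
objective is used on the counts (a Poisson-deviance variant exists but
is off by default).  The final feature set expands the selected
exposure variable with its full lag 0–7 family so the delayed-effect
profile stays interpretable; demographic counts are same-day
vulnerability covariates and are not lagged.

## Models and evaluation

* **GAM**: Poisson family, log link, linear terms for the exposure
  lags and demographics plus a cubic B-spline basis of dimension 50 on
  the day index for the long-term trend (statsmodels `GLMGam`).  The
  smoothing penalty weight defaults to 0 (the library default —
  unpenalised basis) and is recorded in the report; p-values are Wald.
  Prediction clips the day index to the training range, since the
  spline basis is defined on its knots.
* **RF**: `RandomForestRegressor`, 5000 trees, 3 candidate variables
  per split, minimum leaf size 5 (the regression default of the
  reference R implementation whose %IncMSE convention is used).
* **XGB**: 100 trees, depth 3, learning rate 0.05, γ = 0,
  colsample_bytree 0.8, subsample 0.8, min_child_weight 1,
  histogram method, single thread for determinism.  Predictions are
  clipped at zero (counts cannot be negative).

Evaluation uses a seeded random 80/20 split (no temporal blocking — a
time-blocked option exists but is off by default; with a random split
adjacent days land on both sides, so scores should be read as
in-distribution fit, not forecast skill).  R² uses the evaluated
sample's own mean in the denominator.  Grid search scores each
hyperparameter point by mean 10-fold CV RMSE, breaking ties toward
fewer trees, then shallower depth.

**Bootstrap.**  Each of `n_boot` iterations (default 1000) draws n
rows with replacement as the training resample and evaluates on the
out-of-bag rows (~37 % of the table); 95 % CIs are the empirical
2.5/97.5 percentiles.  Resampling-then-resplitting was rejected
because duplicated rows land on both sides of the split and inflate
the tree models' metrics enough to push the point estimate outside its
own CI.  Degenerate resamples (constant response) are skipped and
counted; more than 5 % aborts.  CI tails carry Monte-Carlo error that
shrinks with n_boot; on the default scenario the boosted model's R² CI
width is stable to < 0.02 between 500 and 1000 iterations, while the
random forest's heavier-tailed refit distribution needs more
iterations for that level of tail stability.

**Importance.**  %IncMSE = 100·(MSE_permuted − MSE_base)/MSE_base on
held-out rows, averaged over 10 seeded permutations per variable.
Gain is xgboost's total_gain normalised to sum to one.  SHAP
attributions are exact tree-path-dependent Shapley values: xgboost's
built-in `pred_contribs` for the boosted model and an in-package
numba implementation of the polynomial-time TreeSHAP recursion for
sklearn forests, validated against brute-force subset enumeration;
both satisfy local accuracy (base value + attributions = prediction,
to float64/float32 precision respectively).  Summaries are mean-|SHAP|
over a capped sample of evaluation rows (default 150) because the
algorithm costs O(trees·leaves·depth²) per row.

## Synthetic data generator

The generator emulates a semi-arid Sahelian station and a regional
hospital; its defaults are the package's study conditions.

**Climate.**  TMAX = seasonal curve + AR(1) anomaly + injected excess.
The seasonal curve is an annual plus a semi-annual harmonic (mean
37 °C, amplitudes 2.5 and 2.0 °C, phases at day-of-year 125 and 115),
giving a dominant spring maximum near 41.5 °C and a secondary autumn
maximum — so that with the anomaly the series reaches the mid-40s °C
in spring, as a Matam-like station does.  The anomaly is AR(1) with
coefficient 0.7 and marginal SD 1 °C.  RHMIN follows an anti-phased
harmonic (moist late-August maximum ≈ 50 %, dry-season minimum
≈ 10 %) plus −1.5 %/°C times the TMAX anomaly and noise, clipped to
[2, 100] %.  Ten heatwave episodes (3–7 days, peak excesses
3–5.3 °C) are injected across the five analysis years in the spring
and autumn warm seasons.

*Identifiability convention*: within an injected window the anomaly is
rectified non-negative, and on the single margin day before/after,
non-positive.  Because the threshold is a 90th percentile, a margin
day would otherwise exceed it by chance ~10 % of the time and smear
the injected start/end dates; rectification makes the injected windows
exact ground truth while leaving the additive structure intact
elsewhere.  Detection still finds additional, genuinely stochastic
events (typically ~15 over five years), which is wanted: the analysis
must cope with events it was not told about.

**Admissions.**  The study dataset is produced end-to-end: a 30-year
reference run (same parameters, no injections, shifted seed) yields
the climatology; detection and characterization on the analysis run
yield the daily cumulative-excess exposure; admissions are then drawn
Poisson with log-rate

log μ(t) = β₀ + Σ_k β_k·lag_k(I_cum)(t) + Σ_s γ_s·c_s(t),

so the health signal lives on exactly the exposure scale the pipeline
reconstructs.  Defaults: β₀ = log 6 (≈ 6 admissions/day), lag weights
(0, .005, .01, .06, .035, .05, .02, .005) — peak at lag 3, dip at
lag 4, rebound at lag 5 — per °C·day of exposure.  The demographic
covariates c_s are exogenous daily consultation counts: a Poisson
total (mean 8/day) split multinomially into women (0.52), infants 0–4
(0.13), seniors 65–79 (0.10), seniors 80+ (0.05) and a remainder,
with log-rate effects γ = (0.03, 0.05, 0.06, 0.08) per person.  They
are generated independently of the admission draw so that the
covariates carry signal without leaking the response.  An optional
negative-binomial size parameter adds overdispersion for
stress-testing.  A log-rate above 20 aborts as a mis-scaled scenario.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: diagnostic misclassification and
digitisation noise in hospital records, population growth and
long-term admission trends (the generated rate is trend-free, which is
also why the GAM's unpenalised 50-basis smoother is safe here),
day-of-week and holiday effects, dust/air-quality covariates, and any
spatial structure.  Real-data R² levels also depend on the count
scale: with a mean near six admissions/day, Poisson noise caps
achievable R² well below one regardless of model quality.

## Problem sizes used in the shipped analyses

The default synthetic study spans 1991–2020 (reference) plus
2017–2021 (analysis, ~1,800 usable days after the 7-day lag burn-in).
The test suite and the acceptance script run the forest at 300–500
trees and the bootstrap at 100–1000 iterations, and summarise SHAP on
≤ 150 held-out rows; these are the package's default analysis sizes
for the synthetic scenario and are configurable (`rf_trees`,
`n_boot`, `shap_max_rows`) up to the full 5000-tree / 1000-iteration
settings.

## Known limitations

* The random 80/20 split ignores temporal autocorrelation; scores
  overstate forecast skill.
* Percentile thresholds from a 30-year reference assume stationarity
  of the reference climate.
* The LASSO stage uses a Gaussian objective on counts; selection can
  differ from a Poisson-deviance path when counts are small.
* Path-dependent SHAP splits credit between correlated features
  according to the trees' split choices, so attributions on strongly
  collinear lag families should be read jointly, not per column.
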