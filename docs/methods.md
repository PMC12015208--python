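# Methods

## Exposure model

Grid-point daily minimum/maximum temperatures are averaged (unweighted)
over the points mapped to each ZCTA; the daily mean is the midpoint
`(avg_tmin + avg_tmax)/2` — the standard convention when only a min/max
pair is available. Missing point-days are a hard error (no imputation):
exposure misclassification from silent gap-filling is worse than a loud
failure.

The hot-day threshold is the empirical 97.5th percentile of the ZCTA's
*entire* daily-mean series (all seasons, all years). Quantiles use
linear interpolation at Weibull plotting positions
(`numpy method="weibull"`, p_k = k/(n+1)); the convention is exported as
`exposure.QUANTILE_METHOD` so an external oracle can match thresholds
exactly. On any series with distinct values the share of days at or
below the threshold is within 1/n of 0.975 — one of the package's
property tests.

The exposure window for a birth day is the day itself plus the three
preceding days (lags 0–3), configurable via `window_lag_start` /
`window_length`. Within the window:

* `run_length` — longest run of consecutive days with mean temperature
  *strictly above* the threshold (a tie at the threshold is not hot);
  dichotomised as runs ≥2, ≥3 and =4, a strictly nested family with
  decreasing prevalence.
* `aat` — window mean minus threshold, floored at zero. Days below the
  threshold count negatively *before* the floor: AAT measures the net
  window-level excess, not the sum of exceedances.

Raising any single day's temperature can never decrease either metric
(monotonicity property test).

## Case-crossover design

Event day = birth day; referents = every other day of the same calendar
month falling on the same weekday (3 or 4 by calendar arithmetic, so
strata have 4–5 days). The referent relation is symmetric and
partitions each month into weekday classes — verified by a partition
test. Analysis days are restricted to May 1 – September 30. Strata in
which the covariates are constant contribute nothing to the conditional
likelihood; they are retained in the stratum table and counted
(`n_strata` vs `n_informative`) so that reported case totals match the
population. Births are excluded — and tallied by reason — when they are
not cases of the requested outcome, fall outside the warm season, or
when any stratum day lacks an exposure or adjustment value.

## Pregnancy risk-set adjustment

For outcome risk range [g_lo, g_hi] (28–36 preterm, 37–38 early term):

    W_i = Σ_{g=g_lo}^{g_hi} Z_ig · W_g / Z_i

* Pregnancy start = birth date − 7·(gestational weeks); a pregnancy is
  ongoing on day i iff start ≤ i < birth date (the newborn is an event,
  not at risk, on its birth day); its week on day i is
  floor((i − start)/7).
* `W_g` is the discrete hazard: births at week g divided by births at
  week ≥ g, estimated per state from *all* births (every outcome
  class). A marginal-proportion alternative (`method="marginal"`) is
  available behind a switch; the hazard form is the default because the
  adjustment's target is the birth probability *among pregnancies still
  at risk*.
* `Z_i` includes all ongoing pregnancies, whether or not inside the
  risk range.
* Days with `Z_i = 0` get `W_i = NaN` and any stratum containing such a
  day is excluded and logged.

The vectorized implementation is checked against per-pregnancy
day-by-day enumeration (exact integer agreement of all counts).

Days within 45 weeks of the last observed birth have right-truncated
risk sets (pregnancies that would deliver after the data end are
invisible); such days carry a `boundary_flag`, and `boundary_policy`
chooses between flagging (default), excluding, or ignoring them. The
synthetic studies below are constructed so no analysis day is
truncated.

`W_i` enters the model as a continuous linear covariate. Internally all
covariates are rescaled to unit average within-stratum standard
deviation before fitting (W_i's raw scale is ~10⁻²–10⁻³, which would
make the information matrix badly conditioned); estimates are reported
on the original scale.

## Conditional logistic regression

One case per stratum; log-likelihood
`ℓ(β) = Σ_s [x_case·β − log Σ_{j∈s} exp(x_j·β)]` with analytic gradient
and observed information, maximised by Newton–Raphson from β = 0 with
step-halving (the likelihood is concave, so a short enough step along
the Newton direction always ascends). Convergence: gradient max-norm
< 1e-8 on the scaled covariates, at most 50 iterations. On problems
large enough that float64 accumulation floors the computed gradient
above 1e-8 (|ℓ| in the tens of thousands), a machine-precision-
stationary likelihood with a near-zero gradient (< 1e-5) is also
accepted — for a concave likelihood under a safeguarded ascent step
that is the optimum to working precision. Standard errors come from
the inverse observed information at the MLE.

Monotone likelihoods (perfect separation) are flagged, not raised: a
runaway coefficient during iteration, or — subtler — a "converged"
solution whose gradient vanished only because the exponentials
saturated, detected as a coefficient above 5 within-stratum SDs with a
standard error above 50 on that scale. Flagged fits are reported
non-converged and excluded from pooling.

The solver is validated three ways: brute-force likelihood summation,
an exhaustive grid search over β, and an independent established
conditional-logistic implementation (agreement < 1e-6 on the
coefficient).

### Finite-sample bias under sparse exposure

With heat-wave exposure, only strata containing at least one
positive-AAT (or hot-run) day are informative, and the case day has
prior probability ~1/5. In this sparse, skewed regime the plain
conditional MLE carries the classic O(1/m) sparse-data bias (m =
informative strata): measured by a case-redraw oracle (same strata,
case day redrawn uniformly — an exact null with identical exposure
structure), the mean of β̂ is ≈ −0.037 at m ≈ 50, −0.017 at m ≈ 200,
and ≈ −0.008 at m ≈ 400. This is a property of the estimator, not of
the pipeline; it is negligible at real-data scale (10⁵–10⁶ cases). The
recovery and effect-modification studies are therefore sized so that
m is large enough for the bias to be immaterial, while the null
calibration study also runs at a deliberately modest scale where the
rejection rate (which the bias barely moves, being small against the
per-replicate SE) can be checked cheaply.

## Pooling and heterogeneity

Fixed-effect inverse-variance pooling of per-state log-ORs:
w_k = 1/se_k², pooled β = Σw_kβ_k/Σw_k, pooled se = (Σw_k)^{−1/2}.
Always per-state fits first, pooled afterwards — never one pooled
mega-fit. Heterogeneity across subgroup levels (each level first
pooled across states) is tested with
chi² = Σ w_k (β_k − β_pooled)², df = k−1; at k = 2 this equals the
squared two-group Z statistic exactly. Under a common true β the
heterogeneity p-values are uniform (KS-checked). Random-effects
pooling, meta-regression and I² are out of scope.

## Synthetic data generator

The generator's defaults are the study conditions of the validation
experiments; they are chosen for realism, not convenience.

* **Temperature**: per ZCTA, `μ + A·cos(2π(doy − 197)/365.25) +
  offset_z + AR(1)`, with μ = 17 °C, A = 9 °C (mid-July peak),
  ρ = 0.80, innovation sd 1.6 °C, ZCTA offset sd 1 °C. Grid points add
  independent noise (sd 0.5 °C) around the ZCTA series; tmin/tmax are
  emitted ±5 °C around the mean. ρ and the innovation sd were
  calibrated so the relative-threshold definitions reproduce the
  warm-season frequencies typical of multi-state US studies (~5.6%,
  2.6%, 1.2% of days for runs ≥2/≥3/=4; ~4.2% of days with positive
  AAT, averaging ~1.0 °C) and were frozen before any validation study
  was run.
* **Population**: conception dates with mild sinusoidal seasonality
  (amplitude 0.10, peak around day 250); maternal age groups
  (31/52/17%) and education (25/30/45%); per-ZCTA Social Deprivation
  Index (1–100 centile ranks) and impervious land-cover fraction,
  rank-correlated with the ZCTA temperature offset (warmer ZCTAs more
  deprived/built-up, correlations 0.4/0.5).
* **Births**: from week 20 each pregnancy faces a daily birth
  probability `h_g,daily · exp(β_s · AAT_i)` (capped at 0.99), with
  weekly hazards `W_g` tuned to ~7.8% preterm and ~22% early term
  births and the effect applied in weeks 28–38. β_s can differ by
  subgroup. Because the hazard model is multiplicative in the same AAT
  the analysis measures, the analysis estimand equals the simulated
  β_s. Pregnancies still undelivered after week 44 are forced to
  deliver at week 45 (counted). The exposure-independent phases
  (weeks 20–27 and 39+) are drawn from their exact first-passage
  distributions; only weeks 28–38 are simulated day by day — identical
  in law to full day-by-day simulation, at a third of the cost.
* **Windowing**: temperature is generated with 330 days of padding on
  both sides of the analysis years and conceptions drawn so that every
  pregnancy ongoing on an analysis day is conceived, and delivers,
  inside the simulated window — analysis-day risk sets are complete by
  construction.

What the generator does *not* emulate: real spatial correlation
between neighbouring ZCTAs, humidity or other heat-stress modifiers,
demographic joint distributions (age × education), gestational-age
measurement error and digit preference, labor induction, and secular
trends. Passing validation therefore shows the pipeline estimates what
the generative model encodes — not that any particular real-world
estimate is correct.

## Validation study sizes

* Null calibration: 500 replicates, 1 state × 10 ZCTAs × 500
  pregnancies over 2 warm seasons (ETB outcome, AAT definition).
* Recovery/coverage: 200 replicates at 4000 pregnancies/ZCTA
  (~400 informative strata each) so the estimator's O(1/m) bias is
  immaterial against the Monte-Carlo tolerance.
* Effect modification: 100 replicates, two subgroups (true ORs 1.00
  and 1.05) at 2 states × 50 ZCTAs × 16 000 pregnancies; the scale
  comes from a power calculation — ordering two pooled estimates with
  ~95% probability needs SE(difference) ≈ gap/1.65, i.e. per-arm SE
  ≈ 0.018. The recoverable gap is slightly below log(1.05): referent
  days falling at gestational weeks ≥39 carry no heat effect in the
  generative model (the effect window is weeks 28–38) while the
  conditional-logistic contrast assumes a common effect across all
  stratum days, a mild attenuation intrinsic to the design.

Replicate studies use the early term outcome (three times the case
yield of preterm per simulated pregnancy; identical machinery) and one
temperature grid point per ZCTA with no point noise, so the exposure
the generator applies and the exposure the analysis measures coincide
exactly.

## Numerical and degenerate-input choices

* Exceedance is strict (>); a day exactly at the threshold is not hot.
* Quantiles: Weibull plotting positions (declared above).
* Ties in the first-passage inverse-CDF sampling occur with
  probability zero (continuous uniforms).
* Strata with multiple or zero case days are an error; non-informative
  strata are dropped from the likelihood silently but counted.
* A state-stratum cell that cannot be fitted (no informative strata,
  or a flagged monotone likelihood) is logged and skipped; pooling
  proceeds over the remaining states.
* Empty result sets warn rather than raise.

## Known limitations

* Fixed-effect pooling only; with genuine between-state heterogeneity
  the pooled CI is anti-conservative.
* The W_i adjustment enters linearly; a log-linear option exists but
  no spline/nonlinear form.
* The conditional MLE's sparse-data bias (above) matters below ~200
  informative strata; no Firth-type correction is implemented.
* Exposure assignment ignores residential mobility and within-ZCTA
  temperature heterogeneity, as does the design it implements.
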