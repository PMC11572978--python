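# Methods

This note records the modelling assumptions, parameter conventions and
design choices behind `fertdiff`, and what the synthetic experiments do and
do not demonstrate.

## Data conventions

All tables are tidy CSVs with one row per cell (schemas in
`fertdiff.data_model`). Cohorts and periods are labelled by the **start
year** of their 5-year interval (1955 means 1955–1959) and age groups by
their start age. Education is the four-category DHS-style attainment
scheme `none / primary / secondary / higher`; rate and CFR tables also
accept the code `total` for all-education benchmark series. Rates are
births per woman per year, bounded to [0, 1]; CFR carries a sanity bound
of 15 children per woman. Missing `children_ever_born` is an empty field,
never zero — zero is a valid count.

## Cohort conversion

CFR is 5 × the sum of the six annual rates on the cohort diagonal
(ages 15–19 … 40–44, periods t+15 … t+40). Rates for ages 45–49 are
accepted in surfaces but never summed: completed fertility is defined
through age 40–44. A diagonal with any missing cell raises a typed
incompleteness error listing the missing (age, period) cells rather than
returning a partial sum — a partial CFR is not a meaningful quantity, and
truncated cohorts are handled explicitly by the completion step.
Conversion is linear in the rates and invariant to row order.

## Lee–Carter completion

The classic log-bilinear specification is used, per (country, education)
block independently:

* `a_x` = per-age mean of log rates over the fitted periods;
* `(b_x, k_t)` = leading singular pair of the centered log-rate matrix,
  identified by Σb_x = 1, Σk_t = 0 (the sign convention follows from
  Σb_x > 0, so declining rates give declining k_t and drift ≤ 0);
* drift = (k_T − k_1)/(T − 1); the forecast continues the central
  random-walk-with-drift path k_{T+h} = k_T + h·drift. Point completion
  only — no stochastic prediction intervals, and no second-stage (jump-off)
  re-estimation of k_t.

Numerical choices: zero rates are floored at 1e-6 before logging (with a
logged warning); at least 3 fitted periods are required for the drift to be
meaningful; only periods with all six age groups observed enter the fit;
when assembling a completed diagonal, observed cells always take precedence
over extrapolated ones. On exactly rank-1 log-rate data with linear k_t the
fit and the extrapolation are exact to numerical precision, which is the
oracle the test suite uses.

## Diffusion rates and projection

The rate is defined sign-consistently with the projection recurrence:

    rate_e = (CFR_end − CFR_start) / CFR_start / (SLAMYS_end − SLAMYS_start)

so it is negative when fertility falls while schooling rises, and plugging
the estimate back into CFR·(1 + rate·ΔSLAMYS) reproduces a one-step decline
exactly. (Written with the differences the other way around, the same
quantity appears with a positive sign for a fertility decline; the
implementation uses the form that is internally consistent with the
recurrence and with conventionally reported negative rates.)

Default endpoints are the 1955 and 1985 cohorts, configurable. Rates are
estimated on the continental aggregate and applied per country with that
country's own SLAMYS path — the cross-level design that lets a single set
of education-specific rates drive national forecasts. No rescaling is
applied when aggregate rates meet countries with different jump-off levels.
Projected CFR is floored at zero (the recurrence is linear in ΔSLAMYS and
can cross zero under large schooling gains); the floor logs a warning.

Over k equal steps the endpoint estimator compounds:
estimate = [(1 + r·ΔS)^k − 1]/(k·ΔS) for per-step rate r. It equals r
exactly when the window contains a single nonzero SLAMYS increment — the
configuration used for exact closed-loop tests.

## Out-of-sample validation

Rates are estimated on the window's own endpoint cohorts (first observed
cohort and the truncation cohort), the recurrence is projected to the
horizon, and errors are scored on the held-out cohorts only. Estimation
physically never sees the held-out rows (they are dropped before the
estimator runs; a poisoning test asserts this). Error metrics are MAPE and
RMSE per education group plus the education-weighted aggregate — a
standard scale-aware pair chosen because the protocol itself only defines
the comparison, not the metric. The aggregate uses the *observed*
education weights of the held-out cohorts, so the reported error isolates
fertility-forecast error from composition-forecast error.

## Strata-level Poisson model

Ideal family size (all ever-married women 15–49 with numeric responses —
the numeric-response filter belongs to data preparation, as the microdata
schema only carries counts) or children ever born (women 40–49 only) is
Poisson with

    log μ = β0 + β1[educ] + β2·MYS_s + β3[educ]·MYS_s + U_s (+ urban),

reference category `none`. Stratum mean schooling MYS_s is taken as
supplied, not recomputed from sampled women. Survey design weights are not
applied. Two treatments of U_s:

* **fixed** (default): strata are absorbed as constants in one Poisson
  likelihood. Because MYS_s is itself constant within strata, unrestricted
  stratum dummies are exactly collinear with the intercept and the MYS
  slope; the absorbed constants are therefore parameterized through a
  null-space basis orthogonal to (1, MYS) at the stratum level. This
  identifies (β0, β2) as the stratum-level trend and U_s as the orthogonal
  residual, in a single maximum-likelihood fit (statsmodels Poisson MLE,
  Newton). Note the likelihood-based standard errors of β0 and β2 treat
  the realized strata as fixed: they do not include sampling noise of the
  stratum effects themselves.
* **random**: U_s ~ N(0, σ²), fitted by MAP (Laplace) through
  `statsmodels` `PoissonBayesMixedGLM`. Posterior standard deviations of
  the stratum-level coefficients do include the stratum-effect component,
  which is why the coefficient-recovery coverage study uses this mode.

Prediction curves evaluate exp of the linear predictor with the stratum
term at its reference level — the mean absorbed effect in fixed mode (zero
by construction of the orthogonal basis) and zero in random mode. Grid
points far outside the fitted MYS range log an extrapolation warning
rather than failing. Rank-deficient designs (e.g. an attainment category
absent from the data) raise an error naming the inestimable contrasts; an
all-zero outcome within a category raises a separation diagnostic.

## Synthetic data

The generators are the exact generative inverse of the projection model:
cohort CFR evolves by the recurrence, is split over age groups by a fixed
schedule summing to 1, divided by 5, and laid on exact cohort diagonals
(period = cohort + age start). Noise, when requested, is multiplicative
log-normal on cells — rates are positive and errors plausibly
proportional. All generators draw from named substreams of a single seed,
so adding one generator call never perturbs another's output, and repeated
runs are bit-identical.

The continental scenario (`africa_scenario` / `africa_inputs`) spans
fifteen cohorts 1930–2000 so that the 1970–2015 period window forms a
complete age × period rectangle, mirroring the shape of published
education-age-specific rate series; under that window cohorts 1955–1975
are fully observed and 1980/1985 are truncated. SLAMYS rises 0.5 years per
cohort step (three years across the 1955–1985 analytical window, the order
of the continent's schooling gain over those cohorts), the 1955 jump-off
CFRs are 7.0 / 6.5 / 5.5 / 4.2 children per woman by rising attainment,
and the constant per-step rates are chosen so the *endpoint* diffusion
rates between the 1955 and 1985 cohorts equal the published continental
estimates (−10.2%, −11.09%, −11.57%, −11.64%). Because the construction
makes the log surface exactly rank 1 with linear k_t, the full pipeline
recovers these endpoint rates to machine precision — the scenario is a
closed-loop emulation with known truth, not a reproduction from the
external national datasets.

The microdata generator draws stratum MYS uniformly (default 0–12 years),
education composition from a softmax mixer that shifts mass toward higher
attainment as stratum schooling rises, U_s from N(0, σ²) and outcomes from
the Poisson law; children ever born is generated for ages 40–49 and left
missing otherwise. What the generators do **not** emulate: DHS two-stage
sampling weights and nonresponse, tempo distortions in period rates,
measurement error in schooling, and deviations of real rate surfaces from
low-rank structure. Passing closed-loop tests therefore demonstrates
correctness of the implementation under the model's own assumptions, not
the adequacy of those assumptions for any real population.

## Problem sizes and defaults in the experiments

The packaged experiments use: 7 analytical cohorts (1955–1985) at 5-year
spacing; Lee–Carter fitted on ten 5-year periods (1970–2015); hold-back
validation truncating at the 1965 cohort and projecting to 1985; 100
seeded replicates for the noise-calibration (cell noise sd 2%) and for the
Poisson recovery study (50,000 women in 100 strata, stratum-effect sd
0.1); 10,000 random draws for the aggregation convexity check. These sizes
make every oracle exact or statistically sharp while keeping the whole
suite fast on a single CPU.

## Known limitations

* The Lee–Carter configuration (period-rate extrapolation, then diagonal
  summation) is one of several defensible completion routes; variants that
  complete partial cohort schedules directly would give different numbers
  on real data.
* No uncertainty quantification on diffusion rates or projections; the
  method is a point forecast.
* SLAMYS trajectories are inputs, never forecast endogenously.
* The endpoint rate estimator uses two cohorts only; it is exactly
  identified, hence also sensitive to errors in those endpoint CFRs.
* Education composition weights for aggregation must be supplied (or
  simulated); the package does not project composition.
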