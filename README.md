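# fertdiff

Education-specific cohort fertility forecasting for populations in
demographic transition, built around a schooling-driven diffusion model.

Sub-Saharan Africa still has the world's highest fertility, and the pace of
its decline differs sharply by women's education. Most projection systems
forecast overall fertility first and split it across education groups by
assumption. `fertdiff` implements the direct alternative: forecast each
education group's **completed cohort fertility** (CFR) as a function of the
schooling of the women around them, so that education expansion itself
drives the projected decline. The package is aimed at demographers and
population modellers who need education-stratified cohort fertility inputs
(e.g. for multistate population projections) and a reproducible way to
stress-test the method on synthetic data with known ground truth.

## The method

Let ASFR<sub>i,e,c</sub>(t+i) be the period fertility rate of age group *i*
and education group *e* ∈ {none, primary, secondary, higher} in country
*c*. For a birth cohort labelled by start year *t*:

1. **Cohort conversion.** Sum the rates along the cohort diagonal and scale
   by the 5-year width of each age group:

       CFR(t,e,c) = 5 · Σ_{i=15,20,…,40} ASFR_{i,e,c}(t+i)

   Ages 45–49 are excluded; childbearing is treated as complete in 40–44.

2. **Lee–Carter completion.** The youngest cohorts have not yet reached age
   40–44, so their diagonals are truncated. Per (country, education) the
   log rates are decomposed as log m(x,t) = a_x + b_x·k_t (rank-1 SVD,
   Σb_x = 1, Σk_t = 0), k_t is continued by the central random-walk-with-
   drift path, and the diagonal is summed mixing observed and extrapolated
   cells.

3. **Diffusion rate.** The estimand is the fractional change in CFR per
   unit (year) change in the cohort's Skills in Literacy Adjusted Mean
   Years of Schooling (SLAMYS), measured between two endpoint cohorts
   (default 1955–1959 and 1985–1989):

       rate_e = [CFR_e(1985) − CFR_e(1955)] / CFR_e(1955) / [SLAMYS(1985) − SLAMYS(1955)]

4. **Projection.** Iterate the recurrence along a projected SLAMYS path,
   combining aggregate-level rates with each country's own schooling
   trajectory:

       CFR_e(t+5) = CFR_e(t) · (1 + rate_e · [SLAMYS(t+5) − SLAMYS(t)])

5. **Validation.** Hold-back protocol: estimate rates on an initial cohort
   window, project the held-back cohorts, score MAPE/RMSE per education
   group and for the education-weighted aggregate.

A companion module fits the strata-level Poisson model that motivates the
diffusion interpretation: the ideal family size (or completed births) of a
woman responds to the mean schooling of the women in her survey stratum,
within every attainment level —
log μ = β₀ + β₁[educ] + β₂·MYS_s + β₃[educ]·MYS_s + U_s.

All inputs can be simulated by the `synthetic` module with known generative
parameters, giving closed-loop oracles for every stage.

## Worked example

```python
import pandas as pd
import fertdiff as fd

# 1. Continental inputs shaped like the observed series (periods 1970-2015)
scenario, surface, slamys, weights, _ = fd.africa_inputs()

# 2. Convert period rates to completed cohort fertility
cohorts = [1955 + 5 * i for i in range(7)]
observed, incomplete = fd.convert_all(surface, cohorts)
print("truncated cohorts:", sorted(incomplete["cohort"].unique()))

# 3. Complete the truncated cohorts by Lee-Carter extrapolation
completed = fd.complete_truncated_cohorts(surface, [1980, 1985])
table = pd.concat([observed, completed], ignore_index=True)

# 4. Estimate education-specific diffusion rates (1955 vs 1985 endpoints)
rates = fd.estimate_all_rates(table, slamys, 1955, 1985)
for e, r in rates.items():
    print(f"{e:<10s} {r * 100:+.2f}% per SLAMYS year")

# 5. Hold-back validation: estimate through 1965, forecast 1970-1985
report = fd.out_of_sample(table, slamys, weights, 1965, 1985)
print(report.summary.round(3).to_string(index=False))
```

Output:

```
truncated cohorts: [1980, 1985]
none       -10.20% per SLAMYS year
primary    -11.09% per SLAMYS year
secondary  -11.57% per SLAMYS year
higher     -11.64% per SLAMYS year
education  mape  rmse
     none 0.464 0.026
  primary 0.570 0.028
secondary 0.633 0.026
   higher 0.643 0.020
aggregate 0.542 0.026
```

The four rates say, e.g., that a one-year gain in the continent's
skills-adjusted mean schooling is associated with a 10.2% decline in the
cohort fertility of women with no formal education (the decline is
*steeper* at higher attainment). The validation block shows that rates
estimated from the first three cohorts alone forecast the next four
cohorts with well under 1% mean absolute percentage error on this
noise-free scenario.

The same pipeline is available from the shell:

```bash
fertdiff simulate --seed 0
fertdiff convert  --cohorts 1955:1985:5
fertdiff estimate --start 1955 --end 1985
fertdiff validate --truncate 1965 --horizon 1985
fertdiff strata-fit --outcome ifs --mode fixed --grid 0:12:0.5
```

## Layout

| module | contents |
| --- | --- |
| `fertdiff.data_model` | table schemas, validated CSV read/write |
| `fertdiff.synthetic` | seeded generators for all pipeline inputs |
| `fertdiff.cohort` | period → cohort conversion |
| `fertdiff.lee_carter` | rank-1 log-bilinear fit, extrapolation, completion |
| `fertdiff.diffusion` | rate estimation and the projection recurrence |
| `fertdiff.validation` | weighted aggregation, hold-back validation |
| `fertdiff.poisson` | strata-level Poisson models and prediction curves |
| `fertdiff.config`, `fertdiff.cli` | YAML run config and the `fertdiff` CLI |

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
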