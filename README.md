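# apcpolish

Age–period–cohort (APC) analysis of mortality rate tables: isolate
birth-cohort effects from an age × period grid of annualized rates with the
**multiphase method** (Tukey median polish of log rates, then regression of
the residuals on cohort indicators), and corroborate them with the
**intrinsic estimator**.

The package is aimed at injury and chronic-disease epidemiologists working
with Lexis-style contingency tables — for example deaths per 100,000
population in five-year age groups by five-year calendar periods.  It ships
the published US motorcycle-crash mortality table (14 age groups 15–19 …
80–84 × 8 periods 1975–1979 … 2010–2014, spanning 21 birth cohorts) as a
ready-to-run example.

## The model

A cell of the table is indexed by age group *a*, period *p*, and — because
cohort = period − age — birth cohort *c* on the table's diagonal.  Both
estimators start from the multiplicative model

    log r_ap = μ + α_a + π_p + γ_c + ε_ap .

**Multiphase.**  Median polish iteratively sweeps row (age) and column
(period) medians out of `log r_ap`, leaving residuals in which the additive
age and period effects are removed; a simple linear regression of the
residuals on cohort indicator variables (reference cohort coded out)
estimates γ_c − γ_ref.  Exponentiating gives the cohort **rate ratio**
RR_c = exp(γ̂_c), with 95% CIs from exp(γ̂_c ± 1.96·SE).

**Intrinsic estimator.**  The linear dependency cohort = period − age makes
the effect-coded APC design rank-deficient by exactly one; the intrinsic
estimator is the minimum-norm least-squares solution (Moore–Penrose
pseudoinverse), the unique coefficient vector orthogonal to the design's
null direction, with each effect block summing to zero.

A seeded simulator generates rate/count tables from known multiplicative
age, period, and cohort effects with Poisson count noise, so parameter
recovery and the methods' operating characteristics can be measured.

## Worked example

```python
from apcpolish import MultiphaseAPC, load_motorcycle_rates

table = load_motorcycle_rates()          # 14 ages x 8 periods, 21 cohorts
res = MultiphaseAPC(table, reference="1930–1934").fit()
print(res.summary())
```

```
Multiphase APC fit: table 'all', 14 ages x 8 periods, 21 cohorts
Median polish: 14 sweeps, converged=True
Cohort rate ratios vs 1930–1934 (95% CI, normal quantile)
Birth cohort  Rate ratio  95% CI
1895–1899     0.62        0.27, 1.40
...
1945–1949     1.43        0.97, 2.10
1950–1954     1.47        1.00, 2.16
1955–1959     1.48*       1.01, 2.18
1960–1964     1.48*       1.01, 2.17
...
1995–1999     0.17*       0.07, 0.38
* = P < 0.05
```

Reading the output: after removing age and period effects, the 1955–1959
birth cohort (the peak of the baby-boomer generation) experienced a 48%
higher motorcycle-crash mortality rate than the 1930–1934 reference cohort,
with a 95% CI excluding 1 (starred); cohorts born after 1980 show
significantly *lower* mortality.  The same run is available from the shell:

```sh
apcpolish analyze --out results/          # packaged table, multiphase
apcpolish analyze --method both --out results/
apcpolish plot --out results/fig.svg      # age-specific rate per cohort
apcpolish simulate --seed 1 --out sim/    # synthetic boomer scenario
apcpolish recover --n-reps 200 --seed 1 --out rec/
```

The intrinsic-estimator route:

```python
from apcpolish import IntrinsicEstimatorAPC
ie = IntrinsicEstimatorAPC(table).fit()
ie.cohort_effects          # length-21 sum-to-zero log effects
ie.plot_data()["period"]   # effect series with pointwise CIs
```

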