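# slcma — structured life-course modelling for binary outcomes

Life-course epidemiology asks not just *whether* an exposure matters but
*when*. For repeated binary exposures (here: household poverty measured at
birth, age 4 and age 22 in a Brazilian birth cohort followed to age 30) and a
rare binary outcome (violent offending, homicide), competing hypotheses —
**accumulation** (risk scales with the number of exposed ages), **critical
period** (one age matters and no other), **sensitive period** (one age
matters more, possibly on top of accumulation) and **downward mobility**
(becoming poor) — can be encoded as candidate variables and adjudicated in a
single model selection step. That is the Structured Life Course Modelling
Approach (SLCMA), implemented here for logistic regression.

The package provides, statsmodels-style:

- **`SLCMA`** — the model object. Candidate variables
  `{accumulation, poverty_birth, poverty_child, poverty_adult,
  mobility_birth_adult, mobility_child_adult}` are standardized and entered
  into an L1-penalized logistic path (coordinate descent over a 100-point
  logarithmic penalty grid); adjustment covariates (sex, maternal education,
  maternal age) are forced and never penalized. Candidates enter the path in
  order of evidence; an elbow rule on deviance explained (relative increment
  threshold τ = 0.05, gated by a global likelihood-ratio test at α = 0.05)
  picks the model size k.
- **`SLCMAResults`** — selection path, elbow data and plot, the adjudicated
  hypothesis label, and unpenalized refit odds ratios. Because naive
  intervals after selection are biased, three honest alternatives hang off
  the results: polyhedral **selective inference** (truncated-Gaussian
  intervals conditioned on the selection event, via the one-step
  weighted-least-squares approximation), **Bonferroni**-corrected refits,
  and a **stacked bootstrap** over multiply-imputed datasets (participants
  resampled; each carries all m imputed rows at weight 1/m).
- **`mice_impute`** — multiple imputation by chained equations (predictive
  mean matching for incomes, logistic draws for binary variables).
- **a calibrated synthetic cohort generator** — Gaussian-copula incomes with
  lognormal marginals, covariates on a social gradient, configurable outcome
  mechanisms, MAR attrition and per-offence records — so the entire pipeline
  is testable without the restricted cohort data.
- **descriptives** — cross-tabulations with valid-case percentages, 2×2 odds
  ratios (Woolf intervals), poverty-continuity summaries, offence
  characterizations and the age-crime curve.

## Worked example

```python
from slcma import SLCMA, SimulationParams, simulate_cohort, apply_missingness

params = SimulationParams(n_participants=8000, seed=7)   # calibrated defaults
table = apply_missingness(simulate_cohort(params), params)

model = SLCMA.from_cohort(table, outcome="violent_any", adjusted=True)
res = model.fit(tau=0.05)
print(res.summary())
```

```
Structured Life Course Modelling Approach
=========================================================
n obs:              5364
events:             1140
candidates:         accumulation, poverty_birth, poverty_child, poverty_adult, mobility_birth_adult, mobility_child_adult
covariates forced:  sex, maternal_educ_low, maternal_age_young
entry order:        accumulation, poverty_adult, mobility_child_adult, poverty_birth, mobility_birth_adult
elbow rule:         tau = 0.05, k selected = 2
hypothesis:         sensitive period: early adulthood (with accumulation)
---------------------------------------------------------
variable                   OR            95% CI        p
accumulation             1.31      (1.19, 1.43) 8.34e-09
poverty_adult            1.45      (1.21, 1.76) 9.44e-05
=========================================================
naive Wald intervals; see selective_inference(), bonferroni(),
or the stacked bootstrap for selection-aware uncertainty.
```

Read: each additional age spent in poverty raises the odds of any violent
offending by ~31%, and poverty at age 22 adds a further ~45% on top — the
signature of a sensitive period in early adulthood coexisting with
accumulation (here recovered from a generator whose true log-odds effects
are 0.285 per accumulation step and 0.30 for the adult period).
Selection-aware intervals are wider: `res.selective_inference()` conditions
on the selection event, e.g. 1.28 (1.14, 1.90) for accumulation on the same
data.

A command-line pipeline wraps the same steps
(`slcma simulate | encode | impute | fit | report | all`), writing CSV
tables, the elbow plot and a provenance manifest.

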