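# Methods

This note documents the models implemented in `slcma`, the calibration of
the synthetic cohort generator, the numerical choices, and what the test
suite does and does not establish.

## The selection model

Candidates are the six life-course variables built from three binary
poverty exposures \(p_b, p_c, p_a\) (birth, age 4, age 22):
accumulation \(= p_b + p_c + p_a\), the three period indicators, and two
downward-mobility indicators \((1-p_b)p_a\) and \((1-p_c)p_a\). All six are
entered jointly (a configuration switch drops the mobility pair). Note the
set is deliberately redundant — accumulation is exactly the sum of the
period indicators — which is why selection, not joint estimation, is the
inferential device: critical and sensitive period share the period
indicators and are distinguished after selection.

The path minimizes, over a 100-point logarithmic penalty grid,

\[ -\tfrac1N \ell(\beta_0, \gamma, \beta) + \lambda \lVert\beta\rVert_1 , \]

with \(\ell\) the binomial log-likelihood, \(\gamma\) the unpenalized
coefficients of the forced covariates (sex; maternal education ≤4 years;
maternal age <20) and \(\beta\) the candidate coefficients on variables
standardized to unit variance (penalty fairness between the 0–3 count and
the 0/1 indicators). Optimization is IRLS around a penalized
weighted-least-squares problem solved by cyclic coordinate descent with warm
starts; the grid runs from the smallest penalty with an empty active set
(\(\lambda_{max} = \max_j |x_j^\top(y-\bar p)|/N\), \(\bar p\) from the
covariates-only fit) down to \(10^{-3}\lambda_{max}\), plus an exact
unpenalized endpoint whenever the design has full column rank (with the
full candidate set it does not, by the accumulation identity; the path then
simply ends at the smallest grid penalty). Ties on simultaneous entry are
broken by absolute marginal score then candidate name. Coefficients are
reported per unit of the original scale. A LARS route on the
covariate-residualized linear-probability problem is available as a
cross-check of entry order.

### Elbow rule

Deviance explained is measured against the covariates-only fit by
unpenalized refits of the nested models that follow the path's entry order;
the per-step increments are the jumps of the elbow plot and sum to the total
by construction. Two-part rule:

1. *Gate*: the entered candidates must jointly improve on the covariates-only
   model by a likelihood-ratio test at α = 0.05 (χ² with one degree of
   freedom per entered candidate). A flat elbow plot means nothing is
   selected; without this gate a purely relative rule would always select at
   least one variable, because the first noise increment is always a large
   fraction of a negligible total.
2. *Relative increments*: past the gate, \(k\) is the largest step count such
   that every step \(1..k\) contributes at least τ (default 0.05) of the
   total deviance explained.

Both τ and the gate level are configurable; the elbow data and plot are
always emitted so the automated choice can be audited visually.

### Hypothesis adjudication

A single period indicator alone → critical period at that age; a period
indicator together with accumulation (or with weaker other-period
indicators) → sensitive period at that age; accumulation alone →
accumulation; mobility indicators contribute a mobility component; multiple
components are reported jointly; an empty selection → "no association".
When several period indicators are selected, the largest |log OR| decides
the sensitive age.

## Post-selection inference

Naive Wald intervals after selection are anti-conservative (the package's
null simulations measure ≈83% coverage at the nominal 95% for the
first-selected variable). Three corrections are provided.

**Selective (polyhedral) intervals.** At the grid penalty where the k-th
selected variable entered, the logistic fit is replaced by its one-step
Gaussian working model: \(z = \eta + (y-\mu)/w \sim N(\theta,\,W^{-1})\)
with \(w = \mu(1-\mu)\). The event "this active set with these signs" is a
polyhedron \(\{Az \le b\}\) assembled from the stationarity conditions of
the penalized weighted least-squares problem (sign constraints on active
candidates, subgradient bounds on inactive ones; covariates unpenalized
throughout). For each selected variable the relaxed-refit functional
\(\eta^\top z\) then follows a truncated normal on \([V^-, V^+]\), and the
interval inverts that pivot numerically (bisection with adaptive
bracketing; unbounded truncation yields a one-sided interval, flagged).
This conditions on the fixed-penalty selection event, not the full path
history, and the Gaussian working model is an approximation — both choices
make the intervals mildly conservative, which the coverage simulations
quantify (≈99% empirical coverage at the 95% level on null cohorts of
n = 400) rather than assume. Noise variance comes from the IRLS weights at
the selected penalty.

**Bonferroni.** Refit p-values multiplied by the number of screened
candidates (capped at 1); intervals widened to level \(1-\alpha/6\).

**Stacked bootstrap.** Participants — not rows — are resampled with
replacement; each sampled participant contributes all m imputed versions of
itself at weight 1/m (times its resampling multiplicity) to a weighted
logistic refit of the selected model, so within-person dependence across
imputations is preserved. Percentile intervals (inverse-CDF order
statistics) at 95% and 99%; stars assigned by interval exclusion of 1
(\*: 95% excludes 1; \*\*: 99% excludes 1). B defaults to 1000 (percentile,
not BCa); replicates that fail to converge are dropped and counted, with
more than 5% dropped an error. With m = 1 and complete data this is the
ordinary nonparametric bootstrap, which a test verifies.

## Multiple imputation

Chained equations over the variables with missingness (by construction of
the attrition model: child and adult income), visiting variables in order of
increasing missingness for `n_iterations` sweeps (default 10), with all
study variables — incomes, covariates, and the outcome flags — as
predictors. Incomes use Bayesian linear regression with type-1 predictive
mean matching (posterior draw of coefficients and residual variance; donor
pool of 5 nearest predicted means; imputed values are always observed donor
values, so no negative incomes). Binary variables use a logistic fit with a
posterior-normal coefficient draw and Bernoulli imputation. m defaults
to 20. Chain means per sweep are retained as a drift diagnostic (warn when
the imputed-cell mean moves by more than half an observed SD between first
and last sweep). MNAR mechanisms are out of scope; the generator's attrition
is MAR given covariates, matching the validity condition of the analysis.

## The synthetic cohort generator

The generator is the study condition, not a tuning dial. Defaults emulate a
1982 Brazilian birth cohort (n = 5660 alive at age 10):

- **Incomes**: lognormal marginals (log-SD 0.9 at each age, a typical
  right-skew for household income) linked by a Gaussian copula. Log-means
  are solved so that P(income < 3 minimum wages) is exactly 69.6 / 58.5 /
  37.0% at the three ages. Latent correlations (0.7613, 0.4621, 0.3922) are
  solved so the implied pairwise poverty odds ratios match the published
  continuity values 13.15 (birth→child) and 3.99 (birth→adult), and the
  implied chronic-poverty fraction (poor at all three ages) is 26.1%. The
  third pair is not published in the main text; pinning it to the chronic
  fraction implies a child→adult continuity OR ≈ 3.0, slightly below
  birth→adult — the published marginals and continuity claims cannot all be
  reconciled simultaneously, so the copula treats continuity as free
  parameters calibrated to the printed ORs plus the chronic fraction.
- **Covariates**: male 51.4%, maternal education ≤4 years 33.2%, maternal
  age <20 15.4%. Education and maternal age load on the (negated) latent
  income factor with log-odds gradients 1.0 and 0.5 per SD — poorer families
  have less-educated, younger mothers — with intercepts solved so the
  marginal proportions hold exactly. Without this social gradient,
  MAR-on-covariates attrition would be MCAR with respect to income and
  multiple imputation would have nothing to correct.
- **Outcomes**: Bernoulli draws from
  \(\mathrm{logit}^{-1}(\beta_0 + \beta_{acc}\,acc + \beta_{age}^\top p +
  \beta_{mob}(m_{ba}+m_{ca}) + 1.1\,male + 0.3\,educ + 0.2\,matage)\)
  using the true (pre-attrition) poverty indicators. The declared
  `mechanism` (null / accumulation / critical / sensitive / mobility) forces
  the inactive exposure coefficients to zero. Defaults are the published
  adjusted two-variable structure: β_acc = 0.285 (OR 1.33) and adult-period
  β = 0.30 (OR 1.35), with intercepts −2.7887 (violence) and −6.2432
  (homicide) solved at n = 400 000 so prevalences are 20.5% and 0.9%.
  Homicide draws share the exposure structure with their own intercept, and
  homicide forces violence, so homicide ⊂ violence in every row.
- **Attrition**: logistic MAR propensities in the covariates (default
  loading 0.5 on low maternal education), with intercepts solved per table
  so the marginal missingness rates are exactly 0.159 (age-4 income) and
  0.211 (age-22 income) — about a third of participants incomplete, close
  to the published complete-case fraction. Birth income is never missing
  (enrolment at birth).
- **Offences**: each violent participant draws a zero-truncated negative
  binomial count (dispersion 0.8; untruncated mean solved so the truncated
  mean equals 2907/1151 ≈ 2.53 offences per offender); homicide offenders
  receive 1 + Poisson(58/48 − 1) homicide records. Ages follow a
  discretized Beta(1.8, 1.4) on [10, 30] — offending stays frequent through
  the late twenties, the shape this cohort shows instead of the classic
  adolescent peak-and-decline. Categorical attributes default to the
  published homicide-offence distributions, uncodable-unknown mass included.

What the generator does **not** emulate: neighbourhood/geographic structure,
an adolescent poverty wave (the source cohort has no such measurement),
MNAR attrition, measurement error in criminal records, and within-family
clustering. Passing tests therefore show the *method* behaves as claimed
under a faithful MAR/copula world, not that real-data estimates are
unbiased under record misclassification or MNAR dropout.

## Numerical choices and degenerate inputs

- Poverty boundary: "income < 3" is strict; exactly 3.0 is not poor.
  Tertile cut: smallest observed income c with ≥1/3 of valid incomes ≤ c;
  ties at the cut are poor.
- Percentages round half away from zero to 1 decimal (display convention of
  the published tables; numpy's default half-to-even would print 0.25 as
  0.2).
- 2×2 odds ratios use the Woolf log-normal interval; any zero cell triggers
  the Haldane–Anscombe 0.5 correction, flagged.
- Separation: path coefficients beyond 25 on the standardized scale
  truncate the path at the last stable penalty, flagged; refit separation
  falls back to a profile-likelihood interval.
- Zero-variance candidates are dropped with a warning; an outcome with no
  events (or no non-events) is a validation error, and the pipeline exits
  gracefully with a "no events" manifest entry instead of estimates.
- Seeds: every stochastic component is driven by `numpy.random.default_rng`
  with explicit seeds; missingness and offence generation use derived
  sub-streams so the same cohort can be re-dressed deterministically.

## Problem sizes used by the checks

Monte-Carlo checks are sized to run on one CPU in minutes, as the package's
own test-budget choice: selection consistency uses 100 replicates at
n = 5660 (the acceptance script uses 50); null-coverage of selective vs
naive intervals uses 150 replicates at n = 400; stacked-bootstrap coverage
uses 80 replicates at n = 2000 with m = 10 and B = 200 (script: 40
replicates); the single full-scale analysis uses n = 5660, m = 20, B = 500.
Observed values at these sizes: first-two selection ≈ 99–100%, null
nothing-selected ≈ 96–98%, selective coverage ≈ 99%, naive ≈ 83%,
bootstrap coverage ≈ 92–95% per variable.

## Known limitations

- Selective inference conditions on the fixed-penalty active-set-and-signs
  event under a one-step Gaussian approximation; it is conservative rather
  than exact, and full-path conditioning is not implemented.
- The unpenalized endpoint does not exist for the full six-candidate set
  (accumulation identity); endpoint-vs-ML equivalence holds on
  full-rank designs only.
- Rubin's-rules pooling is deliberately absent: estimates on imputed data go
  through the stacked bootstrap instead.
- The elbow gate makes "no association" a formal test at α = 0.05; with
  very small event counts (e.g. homicide in small cohorts) its power is
  limited and the mobility/period distinction can be unstable.
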