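# Methods

## The statistical problem

The response is a monthly count of newly diagnosed patients, Y₁…Yₙ, with a
covariate vector per month built by aggregating the diagnosed patients'
characteristics: monthly means for numeric variables (age, ordinal clinical
scores) and monthly positive-class proportions for binary ones (married,
smoker, hypertensive, …).  Monthly case counts of chronic disease are
typically overdispersed — Var(Y) > E(Y) — because incidence drifts with
time and case-mix; a Poisson regression then underestimates standard errors
and inflates significance.  The package fits four count families that
differ exactly in how they treat that extra variance, compares them, and
tests whether a small subset of covariates carries the signal.

## Families and likelihoods

All models share the log link log λᵢ = xᵢ′β (intercept first).

**Poisson.** ℓ = Σ yᵢ xᵢ′β − exp(xᵢ′β) − log yᵢ!.

**Negative binomial (NB2).** Poisson–gamma mixture with unit-mean gamma of
shape 1/ν: mean λ, variance λ + νλ².  ℓ uses the exact gamma-function form;
ν → 0 recovers the Poisson.

**Poisson-inverse-Gaussian.** Yᵢ | V ~ Poisson(λᵢV) with V inverse-Gaussian
(mean 1, shape 1/τ): variance λ + τλ².  The pmf is evaluated by the
two-term recurrence

```
p(0) = exp([1 − √(1+2τλ)]/τ)            (the pgf at z = 0)
p(1) = λ (1+2τλ)^(−1/2) p(0)
p(y) = 2τλ/s · (1 − 3/(2y)) · p(y−1) + λ²/s · p(y−2)/(y(y−1)),  s = 1+2τλ
```

All terms are positive (no cancellation); the implementation runs the
recurrence vectorized across observations in linear space with periodic
rescaling, so log-probabilities stay finite arbitrarily deep in the tail.
The recurrence is verified in the test-suite against direct quadrature of
the Poisson × inverse-Gaussian mixture integral to 1e−8 per term.

**Bell.** pmf P(Y=y) = λ_B^y e^(1−e^{λ_B}) B_y / y! with Bell numbers B_y
(number of set partitions of y items, computed exactly as arbitrary-
precision integers via the Bell triangle, entering the likelihood as
log B_y).  Mean λ_B e^{λ_B}, variance λ_B e^{λ_B}(1+λ_B): overdispersion is
built in with no free dispersion parameter.  The regression is
mean-parameterized: λ_{B,i} = W₀(exp(xᵢ′β)) with the principal Lambert W
branch, so exp(xᵢ′β) is the conditional mean exactly as in the other three
families, which keeps coefficients comparable across models.

## Estimation and inference

* Quasi-Newton (L-BFGS-B) on the negative log-likelihood; covariates are
  standardized internally for conditioning and coefficients mapped back.
* Scores in β are analytic for all four families.  For the PIG the score
  uses the mixed-Poisson identity ∂ℓᵢ/∂ηᵢ = yᵢ − tᵢ(yᵢ) with
  tᵢ(y) = (y+1) pᵢ(y+1)/pᵢ(y) (the posterior-mean ratio), so one extra
  pmf evaluation per observation replaces a full numeric gradient.
* Dispersion parameters are optimized as log ν, log τ (positivity by
  construction), analytically for the NB, by central difference for the
  PIG.  Initialization: the Poisson fit seeds β for every family;
  dispersion starts at its method-of-moments value.
* Standard errors: inverse observed information, computed as the Jacobian
  of the analytic score at the optimum (symmetrized).  p-values are
  two-sided normal (Wald).  Fits that stop without meeting the optimizer's
  criteria are flagged `converged_ = False` and excluded from best-model
  selection rather than silently used.
* Degenerate inputs fail loudly: rank-deficient designs raise with the
  names of the collinear columns; non-integer or negative counts are
  rejected; a linear predictor beyond ±80 is treated as divergent.

Numerical identities used as correctness anchors: the intercept-only MLE
puts the fitted mean at ȳ for every family (exactly for Poisson and Bell
via their score equations; for NB and PIG through the mean/dispersion
orthogonality of the mixed-Poisson parameterization, which holds at
interior dispersion estimates); NB and PIG log-pmfs converge to the Poisson
as dispersion → 0.

## Model comparison

* **Dispersion index** DI = s²/ȳ (sample variance, n−1 denominator).
* **Overdispersion test**: after the Poisson fit, aᵢ = ((yᵢ−λ̂ᵢ)² − yᵢ)/λ̂ᵢ
  has mean 0 under equidispersion and mean ≈ νλᵢ under a Var = λ+νλ²
  alternative; z = mean(a)/(sd(a)/√n) is referred to the upper normal tail.
  This auxiliary-statistic test matches the reported test shape (one-sided,
  H₁: dispersion > 1).
* **R²** is 1 − SSres/SStot on the response scale (flagged as undefined for
  a constant response); RMSE and MAE are raw count-scale errors.
* **CV-10** is the pooled out-of-fold RMSE over ten seed-deterministic
  shuffled folds (fold sizes differ by at most one); folds whose training
  design cannot be fitted are skipped with a warning.  Out-of-fold RMSE was
  chosen because the single cross-validation number it produces sits
  slightly above the in-sample RMSE, the signature of generalization error.
* **AIC/BIC** = −2ℓ + 2k and −2ℓ + k·log n with k counting all estimated
  parameters including an estimated dispersion.  Because every family's ℓ
  includes its full constants, criteria are comparable across families.
* **LRT**: −2(ℓ_reduced − ℓ_full) against χ² with df = difference in
  estimated-parameter counts, derived from the actual fits, never assumed.
  A materially negative statistic (non-nested or failed fits) raises.

## The workflow

1. (patient-level input) quality filters → record exclusion → imputation →
   encoding → monthly aggregation;
2. overdispersion test;
3. full fits of all requested families, metric table, coefficient tables;
4. *intersection selection*: keep covariates with Wald p < α (default 0.05)
   in **every** full model;
5. reduced fits on the selected set;
6. LRT full-vs-reduced within one family — by default the family with the
   best full-model AIC — since only same-family pairs are nested;
   cross-family comparison stays with AIC/BIC.

Preprocessing rules: covariates with more than 90% missing are dropped
(strictly "over": exactly 90% is kept), covariates whose modal value covers
at least 90% of observed values are dropped, records with age < 20 or
outside the study window are excluded, then numeric gaps take the column
mean and categorical gaps the column mode (ties broken toward the
lexicographically smallest label, with a warning, for determinism).
Multi-level clinical variables (BMI class, lipid levels, blood-pressure
levels, …) enter as ordered integer scores so each carries one coefficient;
months with zero cases keep y = 0 and carry the across-months covariate
mean so the design stays complete.

## The synthetic generator

`generate_patients` emulates a hospital cohort of diagnosed patients: each
categorical variable is drawn independently from the published category
shares (e.g. 81.8% married, 55.4% male, 45.7% obese), diagnosis years
follow the strongly rising shares 7.7/4.9/3.7/39.6/44.1% over 2018–2022
with uniform month and day, and numeric variables (age, BMI, labs) draw a
category first and then a truncated-normal value inside that category's
clinical bin — so the categorized shares are matched by construction while
the records stay continuous.  HbA1c is drawn above the 6.5% diagnostic
threshold for every record.

`generate_monthly_design` inverts the regression model for simulation
studies: covariates are drawn from a configurable law (Beta for monthly
shares, normal for monthly means, with an optional Gaussian-copula
correlation hook; the default is independence because only marginals are
published), the mean follows the log link, and counts are *exact* draws
from the requested family — gamma–Poisson for NB, Poisson over an
inverse-Gaussian draw for PIG, and the compound-Poisson construction
(a Poisson(e^λ−1) number of zero-truncated Poisson(λ) summands) for Bell.

The default `study_scenario` fixes the study conditions: 18 predictors
(8 binary shares + 10 ordinal scores; HbA1c is excluded because it is the
diagnostic criterion itself and therefore nearly constant across cases),
5 of them active (married, age, BMI, HDL with a protective sign, total
cholesterol), a mean of 1000/60 ≈ 16.7 cases per month, and NB dispersion
ν = 0.4, which reproduces a dispersion index near the reported ≈ 7.4 at
that mean (1 + νλ ≈ 7.7) before the covariate-driven variance is added.
Active effect sizes follow a detectability rule rather than a flat value:
βⱼ = signⱼ · z*/(sdⱼ·√(n·λ/(1+νλ))) with z* = 6 at n = 300, so each active
covariate carries the same Wald signal regardless of its scale (a monthly
share with sd ≈ 0.09 needs a larger coefficient than an ordinal mean with
sd ≈ 0.2).  The intercept includes the lognormal correction −½Σβ²σ² so the
*expected* monthly count, not the count at the covariate means, hits the
target.

What the generator does **not** emulate: between-covariate correlation
(real lipid panels and BMI are correlated), serial dependence between
months, seasonality, and drift in case-mix.  Passing tests therefore
demonstrate correctness of the estimators and procedure, not that the
procedure's selections would be stable on real hospital data.

## Known limitations

* **Intersection selection has a hard multiplicity ceiling.**  A null
  covariate enters the selected set when it is significant at α in all
  four models *on the same data*; since the four Wald statistics are nearly
  perfectly correlated, that joint probability is close to α itself
  (measured ≈ 0.045 at α = 0.05 over 780 null-coefficient replicates).
  With 13 null covariates, the probability that the selected set is
  *exactly* the active set is therefore capped near 0.95¹³ ≈ 0.55 however
  strong the active effects are.  The replicated end-to-end check in the
  test-suite documents this: the full-vs-reduced LRT recovery criterion
  holds (≈ 95% non-significant), while exact-set recovery plateaus at
  ≈ 0.55, far below what intersecting independent tests would give.  Users
  who need family-wise control should lower α or apply a multiplicity
  correction before intersecting.
* Wald p-values (not LRT-based) are used per coefficient; at small n they
  can be slightly anticonservative.
* The PIG dispersion score uses a central difference in log τ; profile
  curvature very near the τ → 0 boundary is obtained from the numeric
  Jacobian and the dispersion SE there should not be interpreted.
* No offsets/exposure, no zero-inflation, no serial-correlation modelling;
  months are exchangeable given covariates.

## Problem sizes used in the test-suite

Distribution oracles run over y ≤ 30 grids and 10⁵-draw sampler checks;
parameter-recovery and calibration checks use 200 replicates at 500 and 200
months respectively; the end-to-end workflow check uses 100 replicates of
the 300-month, 18-predictor scenario.  The full suite runs in a few minutes
on one CPU.
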