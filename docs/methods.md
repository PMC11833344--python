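# Methods

## The question the package answers

Mendelian randomization (MR) treats genetic variants as instrumental
variables: because alleles are assigned at conception, a polygenic risk
score (PRS) for a modifiable exposure provides an exposure contrast
that is largely free of the confounding and reverse causation that
afflict cross-sectional analyses. *Factorial* MR crosses two such
instruments to ask whether two exposures interact. Here the exposures
are body mass index (BMI, kg/m²) and serum 25-hydroxyvitamin D
(25(OH)D, nmol/l), the outcome is psoriasis (binary), and the
interaction scale is *additive*: the relative excess risk due to
interaction,

    RERI = OR11 − OR10 − OR01 + 1,

where OR11 is the odds ratio of the doubly exposed group versus the
doubly unexposed reference and OR10/OR01 the singly exposed groups.
RERI = 0 means the two exposures' odds-ratio effects add exactly;
RERI > 0 means super-additivity. Note that "no interaction" on the
multiplicative (logistic) scale is *not* the additive null: a purely
multiplicative model implies RERI = (OR10 − 1)(OR01 − 1) > 0 whenever
both exposures are harmful.

## Analysis designs

**PRS construction.** A score is the weighted sum of effect-allele
dosages, Σⱼ wⱼ dⱼ, with dosages flipped (2 − d) when the genotype
file counts the other allele. Variants missing from the genotypes are
skipped and reported (`n_variants_used`); missing individual dosages
are mean-imputed per variant from the non-missing samples (equivalent
to 2 × allele frequency), which keeps n constant and is standard PRS
practice. Scores are standardized to mean 0, SD 1 using the population
SD (ddof = 0) of the post-exclusion analysis sample; the ±1/n
difference from the sample-SD convention moves downstream medians at
the 1e-6 scale only.

**2×2 factorial design.** Both scores are dichotomized at their
medians, with values equal to or below the median classified low. The
four groups are coded 0 = BMI score low & vitD score high (lowest
expected risk, the reference), 1 = both low, 2 = both high, 3 = BMI
high & vitD low. Psoriasis is regressed on the three group indicators
plus covariates (default: age, sex, genotyping batch one-hot with first
level dropped, principal components 1–20); RERI is computed from the
three group coefficients, exp(b₃) − exp(b₂) − exp(b₁) + 1.

**Continuous factorial design.** Both standardized scores enter
linearly together with their cross-product. The 25(OH)D score is first
*flipped* (negated) so +1 unit reads "1 SD genetically lower 25(OH)D" —
the risk-increasing orientation; the cross-product is formed after
flipping. RERI is evaluated at the (+1, +1) contrast:
exp(b₁+b₂+b₃) − exp(b₁) − exp(b₂) + 1. The flip is applied only for
continuous modelling, never before median splitting, so the factorial
group definitions stay in trait direction. The "additive term"
exp(b₁+b₂+b₃) — the joint OR of both exposures — is reported alongside.

**Confidence intervals.** The default is the delta method: RERI is a
smooth function of (b₁, b₂, b₃), so Var(RERI) ≈ gᵀΣg with g the
gradient and Σ the coefficient covariance taken from the inverse
observed information of the logistic fit (identical to expected
information under the canonical logit link). A nonparametric percentile
bootstrap over individuals is available (`method="bootstrap"`); at the
sample sizes of interest the two agree closely (the test suite bounds
the SE disagreement at 10% with 2000 resamples at n = 20,000, and
observes well under 1%). All intervals use z = 1.96 exactly.

**Validity rule.** A RERI is directly interpretable only when all three
component ORs exceed 1 (otherwise the reference is not the lowest-risk
corner). Results failing the rule are flagged `valid = False` and
annotated "interpret with caution"; they are still reported.

**Scaling to phenotype units.** To express per-SD genetic effects in
phenotype units (5 kg/m² of BMI, 10 nmol/l of 25(OH)D), each exposure
log-OR is multiplied by target / first-stage effect (the Wald-ratio
construction), the cross-product log-OR by both factors, and the
covariance by the conformable diagonal transform. The RERI is then
*recomputed* from the scaled coefficients — it is non-linear in the
coefficients, so rescaling the RERI itself would be wrong. The test
suite verifies order invariance (scale-then-RERI equals RERI of the
scaled fit).

**Observational counterparts.** Measured 25(OH)D is season-adjusted:
adjusted = raw − mean(draw season) + mean(autumn), with seasons
Dec–Feb/Mar–May/Jun–Aug/Sep–Nov and season means estimated from the
analysis sample itself. The continuous model uses 25(OH)D per 10 nmol/l
*decrease* — implemented as a sign-flip-and-scale of the predictor, not
post-hoc inversion of the OR, so the cross-product's sign convention is
unambiguous — and BMI per 5 kg/m² increase, adjusted for age and sex.
The 2×2 model dichotomizes at 25 nmol/l (deficiency) and 27.5 kg/m²
(the WHO public-health action threshold), both strict on the exposed
side (< 25, > 27.5). Unadjusted group ORs are closed-form cross-product
ratios with Woolf standard errors √(1/a+1/b+1/c+1/d) and no continuity
correction (the intended tables have no small cells); the unadjusted
RERI covariance comes from the saturated logistic fit, which reproduces
the closed-form ORs exactly. Every fit is complete-case on the
variables it uses, so n differs between analysis blocks when BMI or
25(OH)D carry missing values.

**Meta-analysis.** Fixed-effect inverse-variance pooling: weights
∝ 1/se², pooled SE = √(1/Σ(1/se²)).

## Numerical core

Logistic regression is fitted by iteratively reweighted least squares
(Newton steps on the score), tolerance 1e-8 on the largest coefficient
change, at most 100 iterations, starting from zero. Degenerate
outcomes, rank-deficient designs and non-convergence raise errors; a
coefficient drifting past 15 on the logit scale is treated as perfect
separation. The log-likelihood trace is retained and tested to be
non-decreasing. The implementation is cross-checked against
statsmodels' GLM (coefficients, covariance and log-likelihood) in the
test suite rather than delegating to it, so the delta-method inputs are
fully under the package's control. Univariable linear fits (instrument
strength: β per SD, R², F) use closed-form OLS; for these fits
F = (n−2)R²/(1−R²) holds to 1e-8 and is asserted.

## The synthetic cohort generator

No individual-level data from the source biobanks are distributable, so
validation runs on synthetic cohorts built to present the same
statistical surface to the estimators:

- **Genotypes.** Independent biallelic variants, MAF ~ U(0.05, 0.5),
  dosages ~ Binomial(2, MAF); weights ~ N(0, 1). Defaults use 941
  variants for the BMI score and 21 for the 25(OH)D score, the sizes of
  the primary published scores. Because the trait R² is calibrated
  independently of variant count, simulation suites that repeat
  hundreds of cohorts use 100 BMI variants to keep runtimes short —
  a problem-size choice with no effect on any statistical truth.
- **Traits.** trait = mean + slope·z + N(0, σ²) with slope =
  √(R²)·SD(trait) (so a unit-variance score explains exactly the target
  variance share) and σ² = SD²(1 − R²). Defaults: BMI 27.4 (4.8) kg/m²
  with R² = 4.8% (UKB-like; 26.4 (4.4), R² = 3.4% HUNT-like), giving
  first-stage effects of 1.05 and 0.81 kg/m² per SD; season-adjusted
  25(OH)D 54.8 (19.7) nmol/l with R² = 4.6%, giving 4.23 nmol/l per SD.
- **Seasonality.** The stored raw 25(OH)D adds a draw-month offset
  (winter −6, spring −2, summer +7, autumn 0 nmol/l — a realistic
  northern-latitude amplitude, chosen once); `season_adjust` removes it
  up to sampling error, and adjusted season means are exactly equal by
  construction of the adjustment.
- **Covariates.** age ~ N(56.9, 7.9²) (46.1, 16.9² HUNT-like), sex ~
  Bernoulli(0.538), 3 batch levels, 20 standard-normal PCs — all with
  zero effect on the outcome, so adjusted and unadjusted estimates
  should agree within Monte-Carlo error.
- **Missingness.** BMI missing at 0.3%, 25(OH)D at 8.8%, completely at
  random — the rates implied by the source tables' footnotes — to
  exercise complete-case bookkeeping.
- **Outcome.** Group-odds-based: the four factorial groups (from the
  true median split of the generating scores) receive odds
  baseline·{1, OR01, OR10, f11} with f11 = OR10 + OR01 − 1
  (additive null, true RERI exactly 0), f11 = OR10 + OR01 − 1 + RERI*
  (specified RERI), or f11 = OR10·OR01 (multiplicative). The baseline
  odds are solved (Brent) so the cohort-mean probability equals the
  configured prevalence (3.1% UKB-like, 9.0% HUNT-like). Defaults
  OR01 = 1.05, OR10 = 1.08 match the magnitudes seen in the factorial
  groups. The continuous analogue applies the same construction on the
  odds scale: OR10^x1·OR01^x2 (multiplicative) or OR10^x1 + OR01^x2 − 1
  (additive null, positive by a guard at realistic effect sizes), with
  the specified-RERI variant adding RERI*·max(x1,0)·max(x2,0) so the
  (+1, +1) contrast carries the configured RERI exactly.

All randomness flows from a single `numpy` Generator seed; identical
seeds give byte-identical cohorts.

**What the generator does not emulate:** linkage disequilibrium,
relatedness and family structure, assortative mating, population
stratification with real PC structure, confounded score-trait paths
(pleiotropy), non-random missingness, and time-varying effects. Passing
recovery and coverage tests therefore demonstrates that the estimators
are correct and calibrated *under the design assumptions*, not that
those assumptions hold in any real biobank.

## Validation design and problem sizes

- Worked examples: the published dichotomized-analysis contingency
  tables are exact fixtures; closed-form ORs (1.19, 1.58, 1.40), the
  unadjusted combined-group RERI (0.03) and the additive-term product
  (1.03·1.18·1.00 = 1.22) are asserted at 2 decimals, with the RERI
  additionally recomputed through the saturated-logistic route.
- Coverage: 500 additive-null cohorts of n = 20,000; the delta-method
  95% CI for the 2×2 RERI must contain 0 in 95% ± 2.5% of runs
  (observed ≈ 95.6%).
- Recovery: 200 cohorts of n = 50,000 with injected RERI = 0.5
  (OR01 = OR10 = 1.2) and 200 multiplicative cohorts
  (OR10 = 1.19, OR01 = 1.03, implied RERI 0.0057); the mean estimate
  must lie within 3 Monte-Carlo SEs of truth. These sizes keep the
  whole suite in the tens of minutes on one CPU while leaving
  Monte-Carlo error well below the effects being recovered.
- Oracles: statsmodels GLM for the logistic core; closed-form 2×2
  algebra for saturated fits; bootstrap for the delta method;
  brute-force weighted means for the meta-analysis.

## Known limitations

- RERI inference is Wald-type and symmetric; for very rare outcomes or
  small cells a percentile bootstrap (provided) or profile-likelihood
  interval (not provided) is preferable.
- The 2×2 group ORs share a reference group and are correlated; the
  package handles this through the joint covariance, but closed-form
  "per-row" CIs in the observational tables treat rows marginally, as
  the original table layout does.
- Mean imputation of missing dosages attenuates scores slightly when
  missingness is heavy; the generator does not simulate missing
  genotypes, so this path is exercised only by unit tests.
- No support for related individuals (mixed models) or non-European LD
  structure; instruments are taken as given, with no pleiotropy-robust
  estimators (two-stage least squares extensions for binary outcomes
  are out of scope).
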