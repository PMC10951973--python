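# Methods

This note documents the statistical models implemented in `stratmr`, the
generator that stands in for individual-level biobank data, the numerical
conventions, and the design choices made where more than one convention
exists.

## Estimands and scale

The causal parameter throughout is `θ`, the effect of exposure (alcohol,
grams/day) on the log-odds of death. Reported odds ratios use the UK
standard-unit anchor, 1 unit = 8 g of pure alcohol: `OR = exp(8·θ)`. All
causal curves are odds ratios relative to a reference intake of 8 g/day.

## Synthetic-cohort generator

The generator (`stratmr.simulate`) emulates the statistical structure a
one-sample MR analysis of alcohol and mortality relies on, not any
particular cohort's microdata.

**Genotypes.** `n_variants` (default 94) independent biallelic variants,
dosages `Binomial(2, EAF)` with EAF uniform on `maf_range` (default
0.05–0.50): Hardy–Weinberg proportions, linkage equilibrium. Per-allele
weights have exponential magnitudes (scale 0.4 g/day, floor 0.05), all
intake-increasing; the weight table plays the role of discovery-sample
estimates.

**Exposure.** A latent drinking propensity
`L = a0 + b·z + s·(sex−½) − 4c·(health−h̄) + σ·ε`, with `z` the
standardized true-weight score, defaults `a0 = 18` g/day, `b = 2` g/day
per SD of score, `s = 6` g/day (men drink more), `σ = 16` g/day, and `c`
the sick-quitter strength. Under the `constant` mode, exposure is
`max(0, L)` — the per-allele effect on the exposure scale is constant
wherever the censoring at zero does not bind. Under the `proportional`
mode the score acts on the log of a latent intake
(`0.15·z` per SD, log-SD 0.75) which is rescaled to a marginal mean of
18 g/day, so genetic effects grow in proportion to intake level — the
regime in which stratum-specific GRS–exposure coefficients increase with
stratum mean intake. Abstention (exposure set to exactly 0) occurs with
probability `expit(logit(abstainer_fraction) + 2.5c·(health−h̄))`,
i.e. enriched among the ~30% with poor latent health. The defaults give
a marginal intake distribution with mean ≈ 16–18 g/day, SD ≈ 15–19, and
~25–29% zeros.

**Outcomes.** Four causes (CVD, cancer, digestive, respiratory) are
drawn independently given covariates with
`logit P_c = α_c + θ·x + c·health + 0.08·(age−ā) + 0.45·(sex−½) + d_i·γ`,
where `d_i·γ` are optional direct (pleiotropic) variant effects —
zero-mean under `balanced`, positive-mean under `directional`, on a
random 30% of variants. Each `α_c` is calibrated by root-finding
(`brentq`) so the cause attains its share (28/55/6/11%) of the target
all-cause rate (default 7.5%); all-cause death is the union of the four
indicators. Competing-risk structure is deliberately absent: causes are
conditionally independent, mirroring per-cause logistic modelling. With
rates this small the union's log-odds remain essentially linear in
exposure with slope θ.

**Sick-quitter mechanism.** Poor health both raises abstention (and
lowers intake) and adds `c` to every cause's log-odds. With the default
`c = 1` the naive exposure–mortality curve is J-shaped: in a 60,000
person cohort, abstainer mortality exceeds the 4–12 g/day nadir while
heavy drinkers sit far above both. The genetic score is independent of
health, so MR is unaffected beyond sampling noise. The default
*observational* covariate set (`age, sex, smoking, deprivation`)
deliberately excludes the latent health indicator: in real cohorts
self-rated health is an imperfect proxy and residual sick-quitter
confounding survives adjustment, which is the phenomenon the
observational comparator exists to display. Adjusting for
`health_status` directly removes the J-shape, as it should.

**What the generator does not emulate.** Real allele frequencies and
linkage disequilibrium, weight-estimation error shared across analyses,
measurement error in self-reported intake, survival time and competing
risks, household relatedness, and selective participation. Tests passing
on these cohorts show the estimators do what they claim under the
assumed data-generating process; they do not certify robustness to these
additional real-data complications.

**Randomness.** Every draw comes from one `numpy` generator seeded with
`SimConfig.seed`, in fixed order (variants, genotypes, covariates,
exposure noise, abstention, pleiotropy, outcomes by cause); identical
configs reproduce byte-identical tables.

## Instrument construction

Harmonization flips dosage interpretation (`d → 2−d`, `EAF → 1−EAF`)
when the cohort codes the weight table's other allele; strand-ambiguous
(A/T, C/G) variants with EAF in [0.4, 0.6] are excluded as unresolvable,
and variants whose aligned exposure effect is not positive are excluded
by the directional-consistency rule. Both exclusions are logged with
reason codes. Sporadically missing dosages are mean-imputed per variant,
the standard choice that keeps N fixed. Instrument strength is
summarized by the incremental R² of the score over covariates and
`F = t²` of the score term.

## Observational fractional polynomials

Degree-1 and degree-2 FP logistic models are fit by maximum likelihood
over all power combinations from {−2, −1, −0.5, 0, 0.5, 1, 2, 3}
(0 = natural log; a repeated power contributes `x^p` and `x^p ln x`).
Zero intakes are handled by a +1 g/day offset before transformation,
recorded in the fitted model. The non-linearity LRT compares the
best-fitting FP model to the one-parameter linear model with
`df = 2·degree − 1` (each selected power charged for its coefficient and
its selection) under the default `royston` convention, or
`df = max(degree−1, 1)` under `naive`.

A calibration caveat, established by simulation here: because degree-1
candidates have the same dimension as the linear model and the family is
a discrete set of correlated transforms, the selection statistic's null
distribution is far short of the nominal chi-square — under linear truth
the degree-2 statistic's 95th percentile is ≈ 5.1 against a χ²₃
critical value of 7.8, so the default test rejects in under 1% of null
replicates. The test is conservative, never anti-conservative (the
`naive` convention is anti-conservative for degree 2 and should be used
only for comparison). Conservativeness is acceptable for this module's
role: demonstrating that the J-shape is detected (under sick-quitter
confounding the statistic is enormous) while not manufacturing curvature.

Curves are `OR(x) = exp(η(x) − η(8))` using exposure-basis terms only
(hence invariant to covariate centering), with delta-method confidence
bands from the coefficient covariance of the contrast.

## Linear MR

`θ̂ = β̂_ZY / β̂_ZX` with β̂_ZY from logistic and β̂_ZX from linear
regression, both adjusted for the same covariates. The delta-method SE
is second-order by default,
`sqrt(se_ZY²/β_ZX² + β_ZY²·se_ZX²/β_ZX⁴)`; the first-order version is
available. One-sample weak-instrument bias is negligible at the default
instrument strength (F ≈ 1000 at N = 100,000).

Summary-data estimators operate on per-variant `(β_X, se_X, β_Y, se_Y)`:

- **IVW**: weighted regression of β_Y on β_X through the origin, weights
  `se_Y⁻²`; the random-effects variant inflates the SE by
  `max(1, sqrt(Q/(J−1)))`.
- **MR-Egger**: the same regression with an intercept, variants oriented
  so every β_X > 0 (Egger is coding-dependent); the intercept and its
  t(J−2) p-value form the directional-pleiotropy test; multiplicative
  overdispersion floored at 1.
- **Weighted median**: 50% point of the inverse-variance weighted ratio
  distribution with interpolation between adjacent order statistics at
  percentile points `p_j = cum_j − w_j/2`; SE by parametric bootstrap
  (default 1000 draws, seeded).
- **Weighted mode**: argmax of a weighted normal-kernel density over
  ratios, bandwidth `0.9·min(sd, IQR/1.349)·J^(−1/5)` scaled by a
  user factor; the argmax is located on a 2001-point grid and refined by
  bounded scalar optimization; SE by parametric bootstrap.
- **MR-PRESSO**: observed weighted residual sum of squares of each
  variant against its leave-one-out IVW prediction, compared with its
  parametric null distribution (default 1000 simulations); per-variant
  outlier p-values Bonferroni-thresholded at 0.05; the corrected
  estimate is IVW after outlier removal, with a distortion p-value from
  random same-size removals.

## Non-linear MR

**Stratification.** The doubly-ranked assignment sorts by instrument
(ties broken by seeded uniform jitter), cuts consecutive pre-strata of
size K, ranks each pre-stratum by exposure (same tie-break), and sends
the rank-j member to stratum j. When K ∤ N the trailing remainder is
dropped and logged (random reallocation is available); default K = 25.
The residual comparator bins `exposure − fitted(instrument+covariates)`
into K equal-frequency groups and is valid only under a constant
instrument–exposure association.

**LACE.** Within each stratum the GRS–exposure and GRS–outcome
regressions are re-fit with covariates entering directly (not
pre-residualized) and combined by the ratio estimator. Strata smaller
than 50, with one outcome class, with degenerate exposure/score
variance, or with logistic separation are dropped with a logged reason;
more than 20% drops raises a warning (an error in strict mode).

**Meta-regression.** The derivative model
`LACE_k = c0 + c1·t_p(x̄_k + 1)` is fit by weighted least squares
(weights `se⁻²`, treated as known, so the coefficient covariance is
`(XᵀWX)⁻¹` without MSE scaling) for each power p; minimum weighted RSS
selects p. The causal curve integrates the fitted derivative from the
reference, so `h(8) = 0` exactly and a constant derivative gives a
straight line on the log-OR scale; bands are delta-method on the
two-coefficient contrast. The non-linearity statistic is the weighted-RSS
difference between the constant-derivative null and the best FP model.
The default df is 2 — one for the extra coefficient and one for the
power search. This deviates from charging only the coefficient (df 1,
available as `df_convention="coef"`) because simulation under linear
truth (100 replicates, N = 20,000, K = 10) puts the df-1 test at ~14%
type-I error versus ~5% for df-2; the selection step over 8 powers is
real and must be paid for. Cochran's Q across strata and an
inverse-variance-weighted linear trend test are reported alongside.

**A dependence caveat.** Stratum-specific GRS–exposure coefficients are
positively correlated across strata (adjacent correlations ~0.98)
because neighbouring strata are built from neighbouring exposure order
statistics of the same pre-strata. Naive per-replicate significance
tests of a trend across strata (e.g. Spearman p-values) are therefore
anti-conservative; trend diagnostics in the tests and reports use the
magnitude of the rank correlation across replicates instead.

## Validation experiments (what the test suite establishes)

On generator defaults (sick-quitter on, θ = 0.025): the ratio estimator
recovers θ within 2 SE at N = 100,000 and its 95% CI covers θ in ~96% of
N = 20,000 replicates; the doubly-ranked FP test rejects a true linear
effect in ~5% of replicates while the same test on residual strata
rejects in ~36% under proportional genetic effects (and stays nominal
under constant effects); the observational FP analysis of the identical
cohorts rejects linearity overwhelmingly — the J-shape-versus-linear
contrast in one pipeline run. Estimator oracles (closed-form WLS,
brute-force density argmax, hand-enumerated stratification and median
interpolation) pin the arithmetic exactly.

## Problem sizes

Replicate experiments in the test suite use cohorts of 2,000–30,000
individuals and 20–200 replicates per property, and the single-cohort
checks use N = 100,000 — sizes at which every targeted effect is
comfortably identified on a single CPU. The acceptance script reports
the problem size next to every quantity it computes.

## Known limitations

- The LACE meta-regression is degree-1 only (the non-linearity test the
  method prescribes); higher-degree curves are out of scope.
- MR-PRESSO's distortion test uses random same-size removals, a
  simplification of the original's outlier-resampling scheme.
- Logistic-scale noncollapsibility makes the ratio estimand differ
  slightly from the conditional θ when strong unadjusted risk factors
  exist; at the default effect sizes this is well inside sampling noise.
- No survival modelling, competing-risk correction, LD-aware instrument
  selection, Steiger filtering, or multivariable MR.
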