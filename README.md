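# stratmr

Linear and non-linear Mendelian randomisation (MR) for the effect of a
continuous exposure — habitual alcohol intake in grams/day — on binary
mortality outcomes, instrumented by a weighted genetic risk score (GRS).

Conventional observational analyses of alcohol and mortality show a
"J-shaped" curve: abstainers and heavy drinkers die more than moderate
drinkers. The J is largely an artefact of *sick-quitter* bias — people in
poor health stop drinking and also die more. `stratmr` implements the
genetic analysis battery that separates this artefact from causation, and
a synthetic-cohort generator that reproduces the bias mechanism so the
whole pipeline can be exercised and validated without access-restricted
biobank data.

## What it computes

**Instrument.** A weighted score `G_i = Σ_j w_j d_ij` over ~94 biallelic
variants (dosages `d ∈ [0,2]`, discovery-sample weights `w_j`), with
allele harmonization, palindromic-variant exclusion, a
directional-consistency filter, incremental R², F-statistic and a
GRS–confounder scan.

**Observational comparator.** Logistic regression of death on reported
intake with the functional form selected from the fractional-polynomial
(FP) family `p ∈ {-2,-1,-0.5,0,0.5,1,2,3}` (0 = log), tested against
linearity by a likelihood-ratio test.

**Linear MR.** The ratio-of-coefficients (Wald) estimator
`θ̂ = β̂_ZY / β̂_ZX` from GRS–outcome (logistic) and GRS–exposure (linear)
regressions, plus five summary-data estimators for pleiotropy robustness:
IVW (fixed and multiplicative random effects), MR-Egger, weighted median,
weighted mode, and MR-PRESSO. Effects are reported as odds ratios per
standard unit (1 unit = 8 g of pure alcohol): `OR = exp(8·θ)`.

**Non-linear MR (doubly-ranked method).** Participants are ranked by GRS
into pre-strata of size K, then ranked by exposure within each
pre-stratum; the rank-j member of every pre-stratum joins stratum j
(K = 25 by default). Within each stratum the ratio estimator gives the
localized average causal effect (LACE). A weighted FP meta-regression of
LACE on stratum mean intake estimates the derivative of the causal curve,
which is integrated from the 8 g/day reference and tested against a
constant derivative (a linear curve). Unlike the older residual-based
stratification (also provided, as a comparator), the doubly-ranked method
does not assume a constant GRS–exposure association across intake levels.

**Synthetic cohorts.** `simulate_cohort(SimConfig(...))` draws genotypes
in Hardy–Weinberg equilibrium, a zero-inflated right-skewed exposure
(marginal mean ~18 g/day), covariates, and cause-specific death
indicators with log-odds linear in exposure (`theta`, default 0.025 per
g/day), with a configurable sick-quitter confounder and optional
exposure-proportional genetic effects and horizontal pleiotropy.

## Worked example

```python
import numpy as np
from stratmr import (SimConfig, simulate_cohort, harmonize, compute_grs,
                     grs_associations, ratio_estimate,
                     doubly_ranked_strata, stratum_estimates,
                     lace_meta_regression)

sim = simulate_cohort(SimConfig(n_individuals=100_000, seed=11))
alleles = sim.variants[["variant_id", "effect_allele", "other_allele"]
                       ].rename(columns={"effect_allele": "coded_allele"})
aligned, _ = harmonize(sim.variants, alleles)
grs = np.asarray(compute_grs(sim.cohort, aligned))

a = grs_associations(sim.cohort, grs, "all_cause", covariates=["age", "sex"])
est = ratio_estimate(a.beta_zy, a.se_zy, a.beta_zx, a.se_zx)
print(f"OR per 8 g/day: {est.or_per_unit:.3f} "
      f"({est.or_ci[0]:.3f}-{est.or_ci[1]:.3f})")

asg = doubly_ranked_strata(grs, sim.cohort["exposure"].to_numpy(), 25, seed=11)
strata, _ = stratum_estimates(sim.cohort, asg, grs, "all_cause",
                              covariates=["age", "sex"])
fit = lace_meta_regression(strata)
print(f"non-linearity p = {fit.p_nonlinearity:.3f}")
```

Output:

```
OR per 8 g/day: 1.228 (1.078-1.399)
non-linearity p = 0.111
```

The generated cohort has a true effect of `theta = 0.025` log-odds per
g/day, i.e. a true OR per 8 g/day of `exp(0.2) ≈ 1.22`: the ratio
estimate recovers it, and the doubly-ranked test correctly finds no
curvature even though a naive FP fit of the same cohort shows a strong
J-shape (see the pipeline below).

The same analysis runs end-to-end from a YAML config:

```bash
stratmr run-all --config config.yaml --seed 11 --out results/
stratmr report --bundle results/
```

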