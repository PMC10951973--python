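"""Synthetic cohort and summary-statistic generator.

Generates individual-level data with the statistical structure that linear
and non-linear Mendelian-randomisation analyses of alcohol and mortality
assume: ~94 independent biallelic variants in Hardy–Weinberg equilibrium, a
weighted genetic score instrumenting a right-skewed zero-inflated exposure
(grams of alcohol per day), binary cause-specific death indicators whose
log-odds are linear in exposure, and a "sick-quitter" confounder — poor
latent health simultaneously pushes people out of drinking and raises
mortality, producing the familiar J-shaped naive exposure–mortality curve
while leaving the genetic instrument valid.

Two genetic-effect regimes are supported.  Under ``constant`` the score
shifts the exposure additively, so the instrument–exposure association is
the same at every intake level.  Under ``proportional`` the score acts
multiplicatively (on the log of latent intake), so genetic effects are
stronger in strata with higher mean intake — the regime that violates the
constant-effect assumption of residual-based stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import CAUSES, CAUSE_SHARES, SimConfig
from .exceptions import CalibrationError, InvalidParameterError

# Non-complementary allele pairs: strand-unambiguous by construction, so a
# freshly generated weight table never trips the palindromic exclusion.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]


@dataclass
class SimulatedCohort:
    """A realized synthetic cohort.

    Attributes
    ----------
    cohort : pandas.DataFrame
        One row per individual: ``id``, per-variant dosage columns,
        ``exposure`` (g/day), covariates, and one binary ``outcome_*``
        column per cause plus ``outcome_all_cause`` (their union).
    variants : pandas.DataFrame
        The variant-weight table (discovery-scale per-allele effects).
    true : dict
        Realized generative quantities: calibrated per-cause intercepts,
        score mean/SD, the true causal effect, per-variant direct
        (pleiotropic) effects.
    """

    cohort: pd.DataFrame
    variants: pd.DataFrame
    true: dict

    @property
    def dosage_columns(self) -> list[str]:
        return [c for c in self.cohort.columns if c.startswith("rs")]

    def dosages(self) -> np.ndarray:
        return self.cohort[self.dosage_columns].to_numpy(float)


def draw_variants(n_variants: int, maf_range: tuple[float, float],
                  rng: np.random.Generator) -> pd.DataFrame:
    """Draw a variant-weight table.

    Effect-allele frequencies are uniform on ``maf_range``; per-allele
    exposure effects have exponentially distributed magnitudes (many weak
    variants, a few strong ones) with a small floor so no weight is
    exactly zero, all oriented intake-increasing; standard errors are 10%
    of the effect plus a floor.
    """
    lo, hi = maf_range
    if not (0.0 < lo < hi < 1.0):
        raise InvalidParameterError(f"maf_range must be within (0,1): {maf_range}")
    eaf = rng.uniform(lo, hi, size=n_variants)
    beta = rng.exponential(scale=0.4, size=n_variants) + 0.05
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_variants)]
    return pd.DataFrame({
        "variant_id": [f"rs{j + 1:04d}" for j in range(n_variants)],
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": eaf,
        "beta": beta,
        "se": 0.1 * beta + 0.01,
    })


def _genotypes(rng: np.random.Generator, n: int, eaf: np.ndarray) -> np.ndarray:
    eaf = np.asarray(eaf, float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise InvalidParameterError("effect-allele frequencies must lie in (0, 1)")
    return rng.binomial(2, eaf, size=(n, eaf.size)).astype(float)


def simulate_genotypes(n: int, variants: pd.DataFrame, seed: int) -> np.ndarray:
    """Draw an ``n`` x J dosage matrix, binomial(2, EAF) per variant.

    Variants are independent (linkage equilibrium) and in Hardy–Weinberg
    proportions.  Reproducible for a fixed seed.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    return _genotypes(np.random.default_rng(seed), n, variants["eaf"].to_numpy())


def _calibrate_intercept(base_logit: np.ndarray, target: float) -> float:
    """Find alpha with mean(expit(alpha + base_logit)) == target by bisection."""
    if not (0.0 < target < 1.0):
        raise CalibrationError(f"death rate target must be in (0,1); got {target}")

    def f(alpha: float) -> float:
        return float(expit(alpha + base_logit).mean() - target)

    lo, hi = -40.0, 20.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError("intercept calibration bracket failed")
    return float(brentq(f, lo, hi, xtol=1e-10))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    All randomness flows from a single generator seeded with
    ``config.seed``; identical configs give byte-identical output.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals

    # 1. variants & genotypes
    variants = draw_variants(cfg.n_variants, cfg.maf_range, rng)
    dosage = _genotypes(rng, n, variants["eaf"].to_numpy())
    w = variants["beta"].to_numpy()
    raw_score = dosage @ w
    # theoretical moments under HWE so the weight table fully determines them
    eaf = variants["eaf"].to_numpy()
    score_mean = float(2.0 * (w * eaf).sum())
    score_sd = float(np.sqrt((w ** 2 * 2.0 * eaf * (1.0 - eaf)).sum()))
    z = (raw_score - score_mean) / score_sd

    # 2. covariates
    age = rng.uniform(40.0, 70.0, n)
    sex = rng.binomial(1, 0.5, n).astype(float)           # 1 = male
    health = rng.binomial(1, cfg.health_prevalence, n).astype(float)  # 1 = poor
    smoking = rng.binomial(1, 0.3, n).astype(float)
    deprivation = rng.normal(0.0, 1.0, n)

    # 3. exposure
    noise = rng.normal(0.0, 1.0, n)
    health_c = health - cfg.health_prevalence
    if cfg.genetic_effect_mode == "constant":
        propensity = (
            cfg.exposure_mean
            + cfg.grs_effect * z
            + cfg.sex_exposure_effect * (sex - 0.5)
            - 4.0 * cfg.confounding_strength * health_c
            + cfg.exposure_sd * noise
        )
        exposure = np.maximum(0.0, propensity)
    else:  # proportional: log-scale latent intake, rescaled to mean ~18 g/day
        log_latent = (
            cfg.log_grs_effect * z
            + 0.25 * (sex - 0.5)
            + cfg.log_health_effect * cfg.confounding_strength * health_c
            + cfg.log_sigma * noise
        )
        latent = np.exp(log_latent)
        exposure = latent * (cfg.exposure_mean / latent.mean())

    # 4. abstention: probability rises with poor health (sick quitters)
    if cfg.abstainer_fraction > 0:
        abst_logit = logit(cfg.abstainer_fraction) + 2.5 * cfg.confounding_strength * health_c
        abstainer = rng.random(n) < expit(abst_logit)
        exposure = np.where(abstainer, 0.0, exposure)
    else:
        abstainer = np.zeros(n, bool)

    # 5. pleiotropy: direct variant-on-outcome effects
    gamma = np.zeros(cfg.n_variants)
    if cfg.pleiotropy != "none" and cfg.pleiotropy_magnitude > 0:
        n_pleio = int(round(cfg.pleiotropy_fraction * cfg.n_variants))
        idx = rng.choice(cfg.n_variants, size=n_pleio, replace=False)
        if cfg.pleiotropy == "balanced":
            gamma[idx] = rng.normal(0.0, cfg.pleiotropy_magnitude, n_pleio)
        else:
            gamma[idx] = rng.normal(cfg.pleiotropy_magnitude,
                                    cfg.pleiotropy_magnitude / 2.0, n_pleio)
    direct = dosage @ gamma

    # 6. outcomes, one independent draw per cause; all-cause = union
    base = (
        cfg.theta * exposure
        + cfg.confounding_strength * health
        + cfg.age_effect * (age - age.mean())
        + cfg.sex_effect * (sex - 0.5)
        + direct
    )
    alphas: dict[str, float] = {}
    outcomes: dict[str, np.ndarray] = {}
    for cause in CAUSES:
        target = cfg.baseline_death_rate * CAUSE_SHARES[cause]
        alpha = _calibrate_intercept(base, target)
        alphas[cause] = alpha
        p = expit(alpha + base)
        outcomes[cause] = (rng.random(n) < p).astype(np.int8)
    all_cause = np.maximum.reduce([outcomes[c] for c in CAUSES])

    columns: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    for j, vid in enumerate(variants["variant_id"]):
        columns[vid] = dosage[:, j]
    columns.update(
        exposure=exposure, age=age, sex=sex, health_status=health,
        smoking=smoking, deprivation=deprivation,
        outcome_all_cause=all_cause,
    )
    for cause in CAUSES:
        columns[f"outcome_{cause}"] = outcomes[cause]
    cohort = pd.DataFrame(columns)

    true = {
        "theta": cfg.theta,
        "alphas": alphas,
        "score_mean": score_mean,
        "score_sd": score_sd,
        "gamma": gamma.tolist(),
        "abstainer_rate": float(abstainer.mean()),
    }
    return SimulatedCohort(cohort=cohort, variants=variants, true=true)


def simulate_summary_stats(config: SimConfig) -> pd.DataFrame:
    """Generate harmonized two-sample summary statistics.

    Per-variant true exposure effects are drawn as in :func:`draw_variants`;
    observed ``beta_x`` adds exposure-sample noise, and ``beta_y`` is
    ``theta * true + direct`` plus outcome-sample noise, where the direct
    (pleiotropic) effects are zero-mean under ``balanced`` and
    positive-mean under ``directional``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    variants = draw_variants(cfg.n_variants, cfg.maf_range, rng)
    true_bx = variants["beta"].to_numpy()

    gamma = np.zeros(cfg.n_variants)
    if cfg.pleiotropy != "none" and cfg.pleiotropy_magnitude > 0:
        n_pleio = int(round(cfg.pleiotropy_fraction * cfg.n_variants))
        idx = rng.choice(cfg.n_variants, size=n_pleio, replace=False)
        if cfg.pleiotropy == "balanced":
            gamma[idx] = rng.normal(0.0, cfg.pleiotropy_magnitude, n_pleio)
        else:
            gamma[idx] = rng.normal(cfg.pleiotropy_magnitude,
                                    cfg.pleiotropy_magnitude / 2.0, n_pleio)

    se_x = np.full(cfg.n_variants, cfg.summary_se_exposure)
    se_y = np.full(cfg.n_variants, cfg.summary_se_outcome)
    beta_x = true_bx + rng.normal(0.0, 1.0, cfg.n_variants) * se_x
    beta_y = cfg.theta * true_bx + gamma + rng.normal(0.0, 1.0, cfg.n_variants) * se_y
    return pd.DataFrame({
        "variant_id": variants["variant_id"],
        "beta_x": beta_x,
        "se_x": se_x,
        "beta_y": beta_y,
        "se_y": se_y,
    })


def write_cohort(sim: SimulatedCohort, out_dir: str | Path,
                 config: SimConfig | None = None) -> dict[str, Path]:
    """Write cohort, weight table and realized config to ``out_dir``.

    Tables are tab-delimited with a header row; the realized config
    (including calibrated intercepts) is YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.tsv",
        "variants": out / "variant_weights.tsv",
        "config": out / "sim_config.yaml",
    }
    sim.cohort.to_csv(paths["cohort"], sep="\t", index=False)
    sim.variants.to_csv(paths["variants"], sep="\t", index=False)
    realized = {"true": sim.true}
    if config is not None:
        realized["config"] = config.to_dict()
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(realized, fh, sort_keys=False)
    return paths


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stats.to_csv(path, sep="\t", index=False)
    return path
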