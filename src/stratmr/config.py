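"""Simulation and pipeline configuration objects.

``SimConfig`` holds every knob of the synthetic-cohort generator: the
instrument (number of variants, allele-frequency range), the causal effect
of exposure on mortality (``theta``, log-odds per gram/day), the
sick-quitter confounding mechanism, zero-inflation of the exposure, and
horizontal pleiotropy.  Defaults emulate a UK-Biobank-like cohort of
habitual drinkers: right-skewed alcohol intake with marginal mean ~18 g/day
and SD ~19 g/day, an all-cause death rate of ~7.5%, and a weighted
genetic score explaining roughly 1.5% of exposure variance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .exceptions import InvalidParameterError

#: Fractional shares of the all-cause death rate attributed to each cause.
#: Cause-specific indicators are drawn independently given covariates and
#: all-cause mortality is their union, so shares sum to 1 and the union
#: rate falls slightly below ``baseline_death_rate`` (overlap is rare at
#: these rates).
CAUSE_SHARES = {
    "cvd": 0.28,
    "cancer": 0.55,
    "digestive": 0.06,
    "respiratory": 0.11,
}

CAUSES = tuple(CAUSE_SHARES)
OUTCOME_COLUMNS = tuple(f"outcome_{c}" for c in ("all_cause",) + CAUSES)
COVARIATE_COLUMNS = ("age", "sex", "health_status", "smoking", "deprivation")

GENETIC_EFFECT_MODES = ("constant", "proportional")
PLEIOTROPY_MODES = ("none", "balanced", "directional")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_individuals : int
        Cohort size.
    n_variants : int
        Number of biallelic instrument variants (default 94).
    maf_range : tuple of float
        Range of effect-allele frequencies, each in (0, 1).
    theta : float
        Causal effect of exposure on the log-odds of death, per gram/day.
        Applied identically to every cause of death.
    genetic_effect_mode : {"constant", "proportional"}
        Under ``constant`` the genetic score shifts exposure additively, so
        the per-allele effect on the exposure scale is the same at every
        intake level.  Under ``proportional`` the score acts on the log of
        a latent intake, so genetic effects grow with mean intake — the
        regime in which residual-based stratification is biased but
        doubly-ranked stratification remains valid.
    confounding_strength : float
        Strength of the sick-quitter mechanism: poor latent health both
        pushes individuals towards abstention / lower intake and raises
        the log-odds of death by this amount.  Zero disables confounding.
    abstainer_fraction : float
        Approximate marginal probability of being a never/non-drinker
        (exposure forced to exactly zero).
    pleiotropy : {"none", "balanced", "directional"}
        Direct variant-on-outcome effects bypassing the exposure.
    pleiotropy_magnitude : float
        Scale of the direct effects (log-odds per allele); mean of the
        direct-effect distribution under ``directional``, SD under
        ``balanced``.
    pleiotropy_fraction : float
        Fraction of variants receiving a direct effect.
    baseline_death_rate : float
        Target marginal all-cause death rate; per-cause intercepts are
        calibrated by root-finding so each cause attains its share
        (:data:`CAUSE_SHARES`) of this rate.
    seed : int
        Seed of the single generator stream used for all draws.

    Notes
    -----
    The remaining fields are documented generator defaults rather than
    quantities of scientific interest; they control the shape of the
    exposure distribution and the summary-statistic noise level.  Draw
    order from the single stream is fixed: variants, genotypes,
    covariates, exposure noise, abstention, pleiotropy, outcomes by cause.
    """

    n_individuals: int = 10_000
    n_variants: int = 94
    maf_range: tuple[float, float] = (0.05, 0.50)
    theta: float = 0.025
    genetic_effect_mode: str = "constant"
    confounding_strength: float = 1.0
    abstainer_fraction: float = 0.12
    pleiotropy: str = "none"
    pleiotropy_magnitude: float = 0.0
    pleiotropy_fraction: float = 0.3
    baseline_death_rate: float = 0.075
    seed: int = 0

    # --- exposure-model defaults (constant mode) ---
    exposure_mean: float = 18.0          # g/day, latent propensity location
    exposure_sd: float = 16.0            # g/day, residual SD of the propensity
    grs_effect: float = 2.0              # g/day per SD of the genetic score
    sex_exposure_effect: float = 6.0     # g/day, male minus female intake

    # --- exposure-model defaults (proportional mode, log scale) ---
    log_sigma: float = 0.75              # SD of log latent intake
    log_grs_effect: float = 0.15         # log intake per SD of the score
    log_health_effect: float = -0.20     # per unit confounding_strength

    # --- outcome-model defaults ---
    age_effect: float = 0.08             # log-odds per year of age
    sex_effect: float = 0.45             # log-odds, male vs female
    health_prevalence: float = 0.30      # P(poor latent health)

    # --- summary-statistic noise (two-sample emulation) ---
    summary_se_exposure: float = 0.03    # g/day per allele
    summary_se_outcome: float = 0.002    # log-odds per allele

    def validate(self) -> "SimConfig":
        lo, hi = self.maf_range
        if not (0.0 < lo < hi < 1.0):
            raise InvalidParameterError(
                f"maf_range must be ordered within (0, 1); got {self.maf_range}"
            )
        if self.n_variants < 2:
            raise InvalidParameterError("n_variants must be >= 2")
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")
        if not (0.0 <= self.abstainer_fraction < 1.0):
            raise InvalidParameterError("abstainer_fraction must be in [0, 1)")
        if not (0.0 < self.baseline_death_rate < 1.0):
            raise InvalidParameterError("baseline_death_rate must be in (0, 1)")
        if self.genetic_effect_mode not in GENETIC_EFFECT_MODES:
            raise InvalidParameterError(
                f"genetic_effect_mode must be one of {GENETIC_EFFECT_MODES}"
            )
        if self.pleiotropy not in PLEIOTROPY_MODES:
            raise InvalidParameterError(
                f"pleiotropy must be one of {PLEIOTROPY_MODES}"
            )
        if self.pleiotropy != "none" and self.pleiotropy_magnitude < 0:
            raise InvalidParameterError("pleiotropy_magnitude must be >= 0")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise InvalidParameterError("pleiotropy_fraction must be in [0, 1]")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**d).validate()


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (simulate -> reports).

    Either ``sim`` is given (synthetic mode) or the three input paths are.
    """

    sim: Optional[SimConfig] = None
    cohort_path: Optional[str] = None
    weights_path: Optional[str] = None
    summary_stats_path: Optional[str] = None

    outcomes: list[str] = field(default_factory=lambda: ["all_cause"])
    mr_covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    observational_covariates: list[str] = field(
        default_factory=lambda: ["age", "sex", "smoking", "deprivation"]
    )
    k_strata: int = 25
    fp_degree: int = 2
    df_convention: str = "royston"
    reference: float = 8.0
    fp_offset: float = 1.0
    min_stratum_size: int = 50
    n_boot: int = 1000
    n_sim: int = 1000
    bandwidth_factor: float = 1.0
    alpha_outlier: float = 0.05
    seed: Optional[int] = None
    output_dir: str = "stratmr_out"

    def validate(self) -> "RunConfig":
        if self.sim is None and self.cohort_path is None:
            raise InvalidParameterError(
                "either a sim config or a cohort_path is required"
            )
        if self.sim is not None and self.seed is None and self.sim.seed is None:
            raise InvalidParameterError("seed is mandatory in synthetic mode")
        if self.k_strata < 2:
            raise InvalidParameterError("k_strata must be >= 2")
        bad = [o for o in self.outcomes if o not in ("all_cause",) + CAUSES]
        if bad:
            raise InvalidParameterError(f"unknown outcomes: {bad}")
        if not self.outcomes:
            raise InvalidParameterError("outcome list is empty")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown RunConfig fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
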