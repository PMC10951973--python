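"""Weighted genetic risk score construction and instrument validation.

Harmonizes a discovery-sample variant-weight table against the allele
coding of a target cohort, builds the weighted score (the single
instrumental variable for exposure), and runs the standard instrument
checks: variance explained, F-statistic, and a scan for associations with
measured confounders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import FitError, HarmonizationError, InvalidParameterError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window within which a strand-ambiguous (A/T or C/G) variant cannot
#: be resolved and is excluded.
PALINDROMIC_EAF_WINDOW = (0.4, 0.6)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


@dataclass
class InstrumentReport:
    """Instrument-validation summary.

    ``r_squared`` is the incremental proportion of exposure variance
    explained by the score over the covariates alone; ``f_statistic`` is
    the squared t-statistic of the score term (the single-instrument F);
    ``confounder_associations`` holds one row per scanned confounder.
    """

    r_squared: float
    f_statistic: float
    n: int
    confounder_associations: pd.DataFrame


def harmonize(weights: pd.DataFrame, cohort_alleles: pd.DataFrame
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align a weight table to the cohort's allele coding.

    Parameters
    ----------
    weights : DataFrame
        Columns ``variant_id, effect_allele, other_allele, eaf, beta, se``.
    cohort_alleles : DataFrame
        Columns ``variant_id, coded_allele, other_allele`` describing
        which allele each cohort dosage column counts.

    Returns
    -------
    aligned : DataFrame
        Weight rows usable for scoring, with a boolean ``flip`` column
        (dosage must be read as ``2 - d``) and ``eaf`` on the cohort
        coding.
    exclusions : DataFrame
        Columns ``variant_id, reason`` with reason codes ``ambiguous``
        (palindromic, frequency near 0.5), ``direction`` (aligned effect
        not intake-increasing) and ``unmatched`` (absent from the cohort).

    Raises
    ------
    HarmonizationError
        If a cohort allele pair matches the weight table in neither
        orientation.
    """
    req = {"variant_id", "effect_allele", "other_allele", "eaf", "beta", "se"}
    if not req.issubset(weights.columns):
        raise InvalidParameterError(f"weight table must have columns {sorted(req)}")
    cohort_map = cohort_alleles.set_index("variant_id")
    missing = set(cohort_map.index) - set(weights["variant_id"])
    if missing:
        raise HarmonizationError(
            f"cohort variants absent from weight table: {sorted(missing)[:5]}"
        )

    rows, excl = [], []
    lo, hi = PALINDROMIC_EAF_WINDOW
    for rec in weights.itertuples(index=False):
        vid = rec.variant_id
        if vid not in cohort_map.index:
            excl.append((vid, "unmatched"))
            continue
        if _is_palindromic(rec.effect_allele, rec.other_allele) and lo <= rec.eaf <= hi:
            excl.append((vid, "ambiguous"))
            continue
        coded = cohort_map.at[vid, "coded_allele"]
        other = cohort_map.at[vid, "other_allele"]
        if coded == rec.effect_allele and other == rec.other_allele:
            flip = False
        elif coded == rec.other_allele and other == rec.effect_allele:
            flip = True
        else:
            raise HarmonizationError(
                f"variant {vid}: cohort alleles {coded}/{other} incompatible "
                f"with weight table {rec.effect_allele}/{rec.other_allele}"
            )
        if rec.beta <= 0:  # directional-consistency rule
            excl.append((vid, "direction"))
            continue
        rows.append({
            "variant_id": vid,
            "effect_allele": rec.effect_allele,
            "other_allele": rec.other_allele,
            "eaf": 1.0 - rec.eaf if flip else rec.eaf,
            "beta": rec.beta,
            "se": rec.se,
            "flip": flip,
        })
    aligned = pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                          "other_allele", "eaf", "beta", "se",
                                          "flip"])
    exclusions = pd.DataFrame(excl, columns=["variant_id", "reason"])
    return aligned, exclusions


def compute_grs(dosages: pd.DataFrame, aligned: pd.DataFrame) -> pd.Series:
    """Weighted score per individual: ``score_i = sum_j w_j * d_ij``.

    Dosage columns are matched to ``aligned`` by name; flipped variants
    contribute ``2 - d``.  Sporadically missing dosages are mean-imputed
    per variant (on the flipped scale); an all-missing column is an error.
    """
    if len(aligned) == 0:
        return pd.Series(np.zeros(len(dosages)), index=dosages.index, name="grs")
    mat = dosages[aligned["variant_id"].tolist()].to_numpy(float).copy()
    flip = aligned["flip"].to_numpy(bool)
    mat[:, flip] = 2.0 - mat[:, flip]
    if np.isnan(mat).any():
        with np.errstate(invalid="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_means = np.nanmean(mat, axis=0)
        if np.isnan(col_means).any():
            bad = aligned["variant_id"].to_numpy()[np.isnan(col_means)]
            raise InvalidParameterError(
                f"all dosages missing for variant(s): {bad.tolist()}"
            )
        idx = np.where(np.isnan(mat))
        mat[idx] = col_means[idx[1]]
    score = mat @ aligned["beta"].to_numpy(float)
    return pd.Series(score, index=dosages.index, name="grs")


def _design(frame: pd.DataFrame) -> np.ndarray:
    X = sm.add_constant(frame.to_numpy(float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise FitError(
            f"singular design matrix (rank {rank} < {X.shape[1]}); "
            f"columns: {['const'] + list(frame.columns)}"
        )
    return X


def instrument_report(grs: pd.Series, exposure: pd.Series,
                      covariates: pd.DataFrame | None = None,
                      confounders: pd.DataFrame | None = None
                      ) -> InstrumentReport:
    """Instrument strength and confounder scan.

    The exposure is regressed on the score plus covariates;
    ``r_squared`` is the incremental R² of the score and the F-statistic
    is the squared t of the score term.  Each confounder is separately
    regressed on the score with the same covariate adjustment.
    """
    n = len(exposure)
    if n < 30:
        raise InvalidParameterError("instrument report needs >= 30 individuals")
    if float(np.var(exposure)) <= 0:
        raise InvalidParameterError("exposure variance is zero")

    g = np.asarray(grs, float)
    cov = covariates if covariates is not None else pd.DataFrame(index=exposure.index)
    frame = pd.concat([pd.Series(g, index=exposure.index, name="grs"), cov], axis=1)
    X_full = _design(frame)
    y = np.asarray(exposure, float)
    full = sm.OLS(y, X_full).fit()
    if cov.shape[1] > 0:
        reduced = sm.OLS(y, _design(cov)).fit()
        r2 = max(0.0, reduced.ssr - full.ssr) / full.centered_tss
    else:
        r2 = full.rsquared
    t_grs = full.tvalues[1]
    f_stat = float(t_grs ** 2)

    rows = []
    if confounders is not None:
        for name in confounders.columns:
            fit = sm.OLS(np.asarray(confounders[name], float), X_full).fit()
            rows.append({
                "confounder": name,
                "estimate": float(fit.params[1]),
                "se": float(fit.bse[1]),
                "p": float(fit.pvalues[1]),
            })
    scan = pd.DataFrame(rows, columns=["confounder", "estimate", "se", "p"])
    return InstrumentReport(r_squared=float(r2), f_statistic=f_stat, n=n,
                            confounder_associations=scan)


def read_weights(path: str) -> pd.DataFrame:
    """Read a tab-delimited variant-weight file."""
    return pd.read_csv(path, sep="\t")


def write_exclusions(exclusions: pd.DataFrame, path: str) -> None:
    exclusions.to_csv(path, sep="\t", index=False)
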