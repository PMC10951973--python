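"""Conventional observational analysis of exposure and mortality.

Logistic regression of a binary death indicator on reported alcohol
intake, with the functional form chosen from the fractional-polynomial
family and tested against linearity by a likelihood-ratio test.  This is
the analysis whose J-shaped curve motivates the Mendelian-randomisation
comparison: it is fully exposed to sick-quitter confounding.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import FitError, InvalidParameterError
from .fracpoly import FP_POWERS, candidate_powers, fp_basis


@dataclass
class FPModel:
    """A fitted fractional-polynomial logistic model.

    ``coef``/``cov`` cover the exposure basis terms only (the quantities
    needed to draw the exposure–outcome curve); intercept and covariates
    are profiled out of the reported shape.
    """

    degree: int
    powers: tuple[float, ...]
    coef: np.ndarray
    cov: np.ndarray
    deviance: float
    offset: float
    n_params: int                 # total parameters of the fitted model
    exposure_range: tuple[float, float]
    converged: bool = True
    extras: dict = field(default_factory=dict)

    def eta_exposure(self, x: np.ndarray) -> np.ndarray:
        """Exposure-only part of the linear predictor."""
        return fp_basis(np.asarray(x, float), self.powers, self.offset) @ self.coef

    def to_json(self) -> str:
        return json.dumps({
            "degree": self.degree,
            "powers": list(self.powers),
            "coef": self.coef.tolist(),
            "deviance": self.deviance,
            "offset": self.offset,
            "n_params": self.n_params,
        })


@dataclass
class CausalCurve:
    """Odds-ratio curve relative to a reference exposure."""

    grid: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference: float
    extrapolated: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = pd.DataFrame({
            "x": self.grid,
            "or": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })
        if self.extrapolated is not None:
            d["extrapolated"] = self.extrapolated
        return d


def _fit_one(y: np.ndarray, basis: np.ndarray, covmat: np.ndarray | None):
    parts = [np.ones((len(y), 1)), basis]
    if covmat is not None and covmat.shape[1] > 0:
        parts.append(covmat)
    X = np.column_stack(parts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge")
    k = basis.shape[1]
    return res, res.params[1:1 + k], res.cov_params()[1:1 + k, 1:1 + k]


def fit_fp_logistic(outcome: np.ndarray, exposure: np.ndarray,
                    covariates: pd.DataFrame | None = None,
                    degree: int = 2, offset: float = 1.0,
                    family: tuple[float, ...] = FP_POWERS) -> FPModel:
    """Best-fitting FP logistic model of the given degree.

    Searches every power combination of the family (degree 1: 8 models;
    degree 2: 36), fits each by maximum likelihood with the covariates,
    and returns the minimum-deviance model.  Candidates that fail to
    converge are skipped with a warning.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    if y.min() == y.max():
        raise InvalidParameterError("outcome must contain both classes")
    if np.any(x < 0):
        raise InvalidParameterError("exposure must be non-negative")
    covmat = None
    if covariates is not None and covariates.shape[1] > 0:
        covmat = np.asarray(covariates, float)

    best: FPModel | None = None
    for powers in candidate_powers(degree, family):
        basis = fp_basis(x, powers, offset)
        try:
            res, coef, cov = _fit_one(y, basis, covmat)
        except (FitError, np.linalg.LinAlgError) as err:
            warnings.warn(f"FP candidate {powers} skipped: {err}")
            continue
        dev = float(-2.0 * res.llf)
        if best is None or dev < best.deviance:
            best = FPModel(
                degree=degree, powers=powers, coef=np.asarray(coef),
                cov=np.asarray(cov), deviance=dev, offset=offset,
                n_params=len(res.params),
                exposure_range=(float(x.min()), float(x.max())),
            )
    if best is None:
        raise FitError("every FP candidate failed to converge")
    return best


def fit_linear_logistic(outcome: np.ndarray, exposure: np.ndarray,
                        covariates: pd.DataFrame | None = None,
                        offset: float = 1.0) -> FPModel:
    """The linear comparator: a single untransformed exposure term."""
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    if y.min() == y.max():
        raise InvalidParameterError("outcome must contain both classes")
    covmat = None
    if covariates is not None and covariates.shape[1] > 0:
        covmat = np.asarray(covariates, float)
    basis = fp_basis(x, (1.0,), offset)
    res, coef, cov = _fit_one(y, basis, covmat)
    return FPModel(degree=1, powers=(1.0,), coef=np.asarray(coef),
                   cov=np.asarray(cov), deviance=float(-2.0 * res.llf),
                   offset=offset, n_params=len(res.params),
                   exposure_range=(float(x.min()), float(x.max())))


def lrt_nonlinearity(best_fp: FPModel, linear_fit: FPModel,
                     convention: str = "royston") -> tuple[float, int, float]:
    """Likelihood-ratio test of the best FP model against linearity.

    Returns ``(statistic, df, p)`` with statistic = deviance(linear) -
    deviance(best FP).  Degrees of freedom follow the chosen convention:
    ``royston`` charges 2 df per selected power (coefficient + power
    choice), i.e. df = 2*degree - 1 relative to the one-parameter linear
    model; ``naive`` counts only extra coefficients, df = max(degree-1, 1).
    """
    stat = linear_fit.deviance - best_fp.deviance
    if stat < -1e-6:
        raise FitError(
            f"linear deviance below FP family minimum ({stat:.3g}): fit failure"
        )
    stat = max(0.0, float(stat))
    if convention == "royston":
        df = 2 * best_fp.degree - 1
    elif convention == "naive":
        df = max(best_fp.degree - 1, 1)
    else:
        raise InvalidParameterError(f"unknown df convention: {convention}")
    if best_fp.powers == (1.0,) or stat == 0.0:
        p = 1.0
    else:
        p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def shape_curve(model: FPModel, grid: np.ndarray,
                reference: float = 8.0, level: float = 0.95) -> CausalCurve:
    """Odds-ratio curve OR(x) = exp(eta(x) - eta(ref)) with delta-method CI.

    Uses the exposure terms only, so the curve is invariant to covariate
    centering; the reference point must lie in the observed exposure
    range.
    """
    lo, hi = model.exposure_range
    if not (lo <= reference <= hi):
        raise InvalidParameterError(
            f"reference {reference} outside observed exposure range [{lo}, {hi}]"
        )
    grid = np.asarray(grid, float)
    b_grid = fp_basis(grid, model.powers, model.offset)
    b_ref = fp_basis(np.array([reference]), model.powers, model.offset)
    contrast = b_grid - b_ref                       # rows: c(x)
    log_or = contrast @ model.coef
    var = np.einsum("ij,jk,ik->i", contrast, model.cov, contrast)
    sd = np.sqrt(np.maximum(var, 0.0))
    zcrit = sps.norm.ppf(0.5 + level / 2.0)
    return CausalCurve(
        grid=grid,
        odds_ratio=np.exp(log_or),
        ci_low=np.exp(log_or - zcrit * sd),
        ci_high=np.exp(log_or + zcrit * sd),
        reference=reference,
    )
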