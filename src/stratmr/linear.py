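"""Linear Mendelian-randomisation estimators.

One-sample estimation uses the genetic risk score as a single instrument:
GRS–exposure and GRS–outcome regression coefficients combined by the
ratio-of-coefficients (Wald) method.  Two-sample estimation from
per-variant summary statistics provides five pleiotropy-robust
sensitivity estimators: inverse-variance weighted (fixed and
multiplicative-random effects), MR-Egger, weighted median, weighted mode,
and MR-PRESSO.

Causal effects ``theta`` are on the log-odds-per-gram/day scale; reported
odds ratios per standard unit use the UK convention 1 unit = 8 grams of
pure alcohol, OR = exp(8 * theta).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import (FitError, InvalidParameterError, SeparationError,
                         WeakInstrumentError)

GRAMS_PER_UNIT = 8.0
_Z95 = sps.norm.ppf(0.975)


@dataclass
class MREstimate:
    """A causal-effect estimate with normal-theory 95% CI.

    ``theta`` is in log-odds per gram/day; ``or_per_unit`` converts to the
    odds ratio per 8 g/day standard unit.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    n_variants: int
    extras: dict = field(default_factory=dict)

    @property
    def or_per_unit(self) -> float:
        return float(np.exp(GRAMS_PER_UNIT * self.theta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return (float(np.exp(GRAMS_PER_UNIT * self.ci_low)),
                float(np.exp(GRAMS_PER_UNIT * self.ci_high)))

    def to_dict(self) -> dict:
        lo, hi = self.or_ci
        d = {
            "method": self.method, "theta": self.theta, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "or_per_unit": self.or_per_unit,
            "or_ci_low": lo, "or_ci_high": hi,
            "n_variants": self.n_variants,
        }
        d.update({k: v for k, v in self.extras.items()
                  if isinstance(v, (int, float, str, bool, list))})
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class GRSAssociations(NamedTuple):
    beta_zx: float
    se_zx: float
    beta_zy: float
    se_zy: float
    n: int


def _check_stats(stats: pd.DataFrame, min_variants: int, what: str) -> pd.DataFrame:
    req = {"beta_x", "se_x", "beta_y", "se_y"}
    if not req.issubset(stats.columns):
        raise InvalidParameterError(f"summary stats need columns {sorted(req)}")
    if len(stats) < min_variants:
        raise InvalidParameterError(
            f"{what} requires >= {min_variants} variants; got {len(stats)}"
        )
    if (stats["se_x"] <= 0).any() or (stats["se_y"] <= 0).any():
        raise InvalidParameterError("standard errors must be positive")
    return stats


def grs_associations(cohort: pd.DataFrame, grs: np.ndarray | pd.Series,
                     outcome_name: str, covariates: list[str] | None = None,
                     exposure_name: str = "exposure") -> GRSAssociations:
    """GRS–exposure (linear) and GRS–outcome (logistic) coefficients.

    Both regressions adjust for the named covariate columns of ``cohort``.
    """
    cov_names = covariates or []
    y = cohort[f"outcome_{outcome_name}"].to_numpy(float) \
        if f"outcome_{outcome_name}" in cohort.columns \
        else cohort[outcome_name].to_numpy(float)
    if y.min() == y.max():
        raise InvalidParameterError("outcome must contain both classes")
    n = len(cohort)
    if n <= len(cov_names) + 2:
        raise InvalidParameterError("too few rows for the requested adjustment")

    g = np.asarray(grs, float)
    parts = [np.ones(n), g]
    for c in cov_names:
        parts.append(cohort[c].to_numpy(float))
    X = np.column_stack(parts)

    lin = sm.OLS(cohort[exposure_name].to_numpy(float), X).fit()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            logi = sm.Logit(y, X).fit(disp=0, maxiter=100)
        if not logi.mle_retvals.get("converged", False):
            raise SeparationError(
                "logistic fit did not converge; possible separation — "
                "a larger sample may be needed"
            )
    except PerfectSeparationError as err:
        raise SeparationError(f"perfect separation in logistic fit: {err}") from err
    except np.linalg.LinAlgError as err:
        raise SeparationError(f"singular information matrix in logistic fit: {err}") from err
    if not np.isfinite(logi.bse[1]):
        raise SeparationError("non-finite GRS standard error in logistic fit")
    return GRSAssociations(
        beta_zx=float(lin.params[1]), se_zx=float(lin.bse[1]),
        beta_zy=float(logi.params[1]), se_zy=float(logi.bse[1]), n=n,
    )


def ratio_estimate(beta_zy: float, se_zy: float, beta_zx: float, se_zx: float,
                   order: str = "second") -> MREstimate:
    """Ratio-of-coefficients (Wald) estimate theta = beta_ZY / beta_ZX.

    The delta-method SE is second-order by default,
    sqrt(se_zy^2/beta_zx^2 + beta_zy^2 se_zx^2 / beta_zx^4); ``order="first"``
    drops the instrument-uncertainty term.
    """
    if beta_zx == 0:
        raise WeakInstrumentError("beta_ZX is zero; ratio undefined")
    theta = beta_zy / beta_zx
    if order == "first":
        se = abs(se_zy / beta_zx)
    elif order == "second":
        se = float(np.sqrt(se_zy ** 2 / beta_zx ** 2
                           + beta_zy ** 2 * se_zx ** 2 / beta_zx ** 4))
    else:
        raise InvalidParameterError("order must be 'first' or 'second'")
    return MREstimate("ratio", float(theta), se,
                      float(theta - _Z95 * se), float(theta + _Z95 * se),
                      n_variants=1)


def _ratio_and_weights(stats: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant ratios and inverse-variance weights (delta method)."""
    bx = stats["beta_x"].to_numpy(float)
    by = stats["beta_y"].to_numpy(float)
    sx = stats["se_x"].to_numpy(float)
    sy = stats["se_y"].to_numpy(float)
    if np.any(bx == 0):
        raise WeakInstrumentError("zero beta_x; per-variant ratio undefined")
    r = by / bx
    var = sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4
    return r, 1.0 / var


def ivw(stats: pd.DataFrame, model: str = "random",
        enforce_min: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Fixed effect: WLS of beta_y on beta_x through the origin with weights
    1/se_y^2.  Random effects inflate the SE multiplicatively by
    max(1, sqrt(Q/(J-1))) where Q is the IVW heterogeneity statistic.
    """
    need = {"fixed": 2, "random": 3}.get(model)
    if need is None:
        raise InvalidParameterError("model must be 'fixed' or 'random'")
    stats = _check_stats(stats, need if enforce_min else 1, f"IVW ({model})")
    bx = stats["beta_x"].to_numpy(float)
    by = stats["beta_y"].to_numpy(float)
    w = 1.0 / stats["se_y"].to_numpy(float) ** 2
    s2 = float((w * bx ** 2).sum())
    if s2 == 0:
        raise WeakInstrumentError("all beta_x are zero")
    theta = float((w * bx * by).sum() / s2)
    se = float(1.0 / np.sqrt(s2))
    j = len(stats)
    q = float((w * (by - theta * bx) ** 2).sum())
    scale = 1.0
    if model == "random" and j > 1:
        scale = max(1.0, float(np.sqrt(q / (j - 1))))
    se *= scale
    return MREstimate(f"ivw_{model}", theta, se,
                      theta - _Z95 * se, theta + _Z95 * se, j,
                      extras={"Q": q, "overdispersion": scale})


def egger(stats: pd.DataFrame) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    Variants are oriented so every beta_x is positive (Egger is not
    invariant to allele coding); the intercept estimates the average
    directional pleiotropy and its p-value is the pleiotropy test.  SEs
    use a multiplicative overdispersion floor of 1 and t(J-2) inference.
    """
    stats = _check_stats(stats, 3, "MR-Egger")
    flip = np.sign(stats["beta_x"].to_numpy(float))
    if np.any(flip == 0):
        raise WeakInstrumentError("zero beta_x cannot be oriented")
    bx = stats["beta_x"].to_numpy(float) * flip
    by = stats["beta_y"].to_numpy(float) * flip
    if np.ptp(bx) == 0:
        raise InvalidParameterError("no spread in beta_x: Egger slope unidentified")
    w = 1.0 / stats["se_y"].to_numpy(float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    j = len(bx)
    rss_w = float((w * resid ** 2).sum())
    scale = max(1.0, np.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(xtwx) * scale ** 2
    se_int, se_slope = np.sqrt(np.diag(cov))
    tcrit = sps.t.ppf(0.975, j - 2)
    intercept = float(coef[0])
    theta = float(coef[1])
    p_int = float(2 * sps.t.sf(abs(intercept / se_int), j - 2))
    return MREstimate(
        "egger", theta, float(se_slope),
        theta - tcrit * se_slope, theta + tcrit * se_slope, j,
        extras={"intercept": intercept, "intercept_se": float(se_int),
                "intercept_p": p_int, "overdispersion": float(scale)},
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    p = cum - w / 2.0
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    i = int(np.searchsorted(p, 0.5) - 1)
    return float(r[i] + (r[i + 1] - r[i]) * (0.5 - p[i]) / (p[i + 1] - p[i]))


def _parametric_boot(stats: pd.DataFrame, point_fn, n_boot: int, seed: int
                     ) -> float:
    rng = np.random.default_rng(seed)
    bx0 = stats["beta_x"].to_numpy(float)
    by0 = stats["beta_y"].to_numpy(float)
    sx = stats["se_x"].to_numpy(float)
    sy = stats["se_y"].to_numpy(float)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bx = rng.normal(bx0, sx)
        by = rng.normal(by0, sy)
        bx = np.where(bx == 0, 1e-300, bx)
        r = by / bx
        var = sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4
        est[b] = point_fn(r, 1.0 / var)
    return float(est.std(ddof=1))


def weighted_median(stats: pd.DataFrame, n_boot: int = 1000, seed: int = 0
                    ) -> MREstimate:
    """Weighted-median estimate: the 50% point of the inverse-variance
    weighted empirical distribution of per-variant ratios, interpolated
    between adjacent order statistics.  Consistent when at least half the
    weight comes from valid instruments.  SE by parametric bootstrap.
    """
    stats = _check_stats(stats, 3, "weighted median")
    r, w = _ratio_and_weights(stats)
    theta = _weighted_median_point(r, w)
    se = _parametric_boot(stats, _weighted_median_point, n_boot, seed)
    return MREstimate("weighted_median", theta, se,
                      theta - _Z95 * se, theta + _Z95 * se, len(stats),
                      extras={"n_boot": n_boot})


def _mode_bandwidth(ratios: np.ndarray, factor: float) -> float:
    s = ratios.std(ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    return factor * 0.9 * spread * len(ratios) ** (-1 / 5)


def _weighted_mode_point(ratios: np.ndarray, weights: np.ndarray,
                         factor: float = 1.0) -> float:
    w = weights / weights.sum()
    h = _mode_bandwidth(ratios, factor)
    if h <= 0 or np.ptp(ratios) == 0:
        # degenerate spread: the density is a point mass
        return float(ratios[0])

    def neg_density(x: float) -> float:
        return -float((w * np.exp(-0.5 * ((x - ratios) / h) ** 2)).sum())

    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 2001)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(neg_density, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def weighted_mode(stats: pd.DataFrame, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimate: argmax of a weighted normal-kernel density
    over per-variant ratios, bandwidth by a modified Silverman rule scaled
    by ``bandwidth_factor``.  Consistent when the largest homogeneous
    cluster of variants is valid.  SE by parametric bootstrap.
    """
    if bandwidth_factor <= 0:
        raise InvalidParameterError("bandwidth_factor must be > 0")
    stats = _check_stats(stats, 3, "weighted mode")
    r, w = _ratio_and_weights(stats)
    theta = _weighted_mode_point(r, w, bandwidth_factor)
    se = _parametric_boot(
        stats, lambda rr, ww: _weighted_mode_point(rr, ww, bandwidth_factor),
        n_boot, seed)
    return MREstimate("weighted_mode", theta, se,
                      theta - _Z95 * se, theta + _Z95 * se, len(stats),
                      extras={"bandwidth_factor": bandwidth_factor,
                              "n_boot": n_boot})


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimate for each variant."""
    s1 = (w * bx * by).sum()
    s2 = (w * bx ** 2).sum()
    num = s1 - w * bx * by
    den = s2 - w * bx ** 2
    if np.any(den <= 0):
        raise WeakInstrumentError("leave-one-out IVW undefined")
    return num / den


def mr_presso(stats: pd.DataFrame, n_sim: int = 1000,
              alpha_outlier: float = 0.05, seed: int = 0,
              model: str = "random") -> MREstimate:
    """MR-PRESSO: pleiotropy residual sum of squares and outlier test.

    The global test compares the observed weighted RSS of each variant
    against its leave-one-out IVW prediction with the RSS distribution
    under ``n_sim`` parametric simulations from the no-pleiotropy model.
    Per-variant outlier p-values are Bonferroni-thresholded at
    ``alpha_outlier``; the corrected estimate is IVW after removing
    flagged variants, with a distortion test comparing raw and corrected
    estimates against removal of random variant subsets.
    """
    stats = _check_stats(stats, 4, "MR-PRESSO")
    rng = np.random.default_rng(seed)
    bx = stats["beta_x"].to_numpy(float)
    by = stats["beta_y"].to_numpy(float)
    sx = stats["se_x"].to_numpy(float)
    sy = stats["se_y"].to_numpy(float)
    w = 1.0 / sy ** 2
    j = len(bx)

    theta_loo = _loo_ivw(bx, by, w)
    obs_res2 = w * (by - bx * theta_loo) ** 2
    rss_obs = float(obs_res2.sum())

    # parametric simulations under no pleiotropy
    exp_y = bx * theta_loo
    sim_res2 = np.empty((n_sim, j))
    for s in range(n_sim):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(exp_y, sy)
        tl = _loo_ivw(bxs, bys, w)
        sim_res2[s] = w * (bys - bxs * tl) ** 2
    rss_sim = sim_res2.sum(axis=1)
    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))

    pv = (1 + (sim_res2 >= obs_res2[None, :]).sum(axis=0)) / (n_sim + 1)
    flagged = np.where(pv * j < alpha_outlier)[0]
    if len(flagged) == j:
        raise FitError("MR-PRESSO flagged every variant; no corrected model")

    raw = ivw(stats, model=model, enforce_min=False)
    if len(flagged) > 0:
        keep = stats.drop(stats.index[flagged])
        corrected = ivw(keep, model=model, enforce_min=False)
        # distortion test: random subsets of the same size
        n_draw = min(n_sim, 1000)
        dist = np.empty(n_draw)
        for s in range(n_draw):
            drop = rng.choice(j, size=len(flagged), replace=False)
            sub = stats.drop(stats.index[drop])
            dist[s] = ivw(sub, model=model, enforce_min=False).theta - raw.theta
        obs_dist = corrected.theta - raw.theta
        distortion_p = float((1 + (np.abs(dist) >= abs(obs_dist)).sum())
                             / (n_draw + 1))
    else:
        corrected = raw
        distortion_p = float("nan")

    return MREstimate(
        "presso", corrected.theta, corrected.se,
        corrected.ci_low, corrected.ci_high, j - len(flagged),
        extras={"global_p": global_p,
                "outlier_indices": flagged.tolist(),
                "outlier_p": pv.tolist(),
                "distortion_p": distortion_p,
                "raw_theta": raw.theta, "raw_se": raw.se},
    )


def read_summary_stats(path: str) -> pd.DataFrame:
    """Read tab-delimited summary statistics (beta_x, se_x, beta_y, se_y)."""
    return pd.read_csv(path, sep="\t")


def all_summary_estimates(stats: pd.DataFrame, n_boot: int = 1000,
                          n_sim: int = 1000, bandwidth_factor: float = 1.0,
                          alpha_outlier: float = 0.05, seed: int = 0
                          ) -> list[MREstimate]:
    """Run the five summary-data estimators (IVW twice: fixed + random)."""
    return [
        ivw(stats, "fixed"),
        ivw(stats, "random"),
        egger(stats),
        weighted_median(stats, n_boot=n_boot, seed=seed),
        weighted_mode(stats, bandwidth_factor=bandwidth_factor,
                      n_boot=n_boot, seed=seed + 1),
        mr_presso(stats, n_sim=n_sim, alpha_outlier=alpha_outlier,
                  seed=seed + 2),
    ]
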