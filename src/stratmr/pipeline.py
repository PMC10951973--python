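"""End-to-end pipeline: simulate/load -> GRS -> observational -> MR.

``run`` executes, per outcome, the full analysis sequence — observational
fractional-polynomial fit with non-linearity test, linear MR (one-sample
ratio estimate plus the summary-data estimators when summary statistics
are available), and non-linear MR by doubly-ranked stratification — and
writes a machine-readable bundle with a checksummed manifest.
``render_report`` turns a bundle into per-outcome figures and a text
summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import grs as grs_mod
from . import linear, nonlinear, observational, simulate
from .config import RunConfig
from .exceptions import InvalidParameterError, StratMRError

log = logging.getLogger("stratmr")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate_columns(cohort: pd.DataFrame, config: RunConfig) -> None:
    needed = set(config.mr_covariates) | set(config.observational_covariates)
    needed |= {"exposure"}
    needed |= {f"outcome_{o}" for o in config.outcomes}
    missing = sorted(needed - set(cohort.columns))
    if missing:
        raise InvalidParameterError(f"cohort is missing columns: {missing}")


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = simulate.simulate_cohort(config.sim)
        stats = simulate.simulate_summary_stats(config.sim)
        return sim.cohort, sim.variants, stats
    cohort = pd.read_csv(config.cohort_path, sep="\t")
    variants = (grs_mod.read_weights(config.weights_path)
                if config.weights_path else None)
    stats = (linear.read_summary_stats(config.summary_stats_path)
             if config.summary_stats_path else None)
    return cohort, variants, stats


def run(config: RunConfig) -> dict:
    """Execute the pipeline and write the report bundle.

    Returns the bundle as a dict; every numerical output is also written
    under ``config.output_dir`` together with a manifest recording the
    resolved config, seed, and SHA-256 of each output file.
    """
    config = config.validate()
    seed = config.seed if config.seed is not None else (
        config.sim.seed if config.sim is not None else 0)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    cohort, variants, stats = _load_inputs(config)
    _validate_columns(cohort, config)
    bundle: dict = {"outcomes": {}, "errors": {}}

    # --- GRS stage ---
    if variants is not None:
        cohort_alleles = variants[["variant_id", "effect_allele",
                                   "other_allele"]].rename(
            columns={"effect_allele": "coded_allele"})
        aligned, exclusions = grs_mod.harmonize(variants, cohort_alleles)
        score = grs_mod.compute_grs(cohort, aligned)
        report = grs_mod.instrument_report(
            score, cohort["exposure"],
            covariates=cohort[config.mr_covariates],
            confounders=cohort[[c for c in ("smoking", "deprivation",
                                            "health_status")
                                if c in cohort.columns]],
        )
        bundle["instrument"] = {
            "n_variants": int(len(aligned)),
            "n_excluded": int(len(exclusions)),
            "r_squared": report.r_squared,
            "f_statistic": report.f_statistic,
            "confounder_scan": report.confounder_associations.to_dict("records"),
        }
        exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    elif "grs" in cohort.columns:
        score = cohort["grs"]
        bundle["instrument"] = {"note": "precomputed grs column used"}
    else:
        raise InvalidParameterError("no weight table and no 'grs' column")
    grs_arr = np.asarray(score, float)
    log.info("GRS stage done (N=%d, %.1fs)", len(cohort), time.time() - t_start)

    grid = np.linspace(0.0, float(np.percentile(cohort["exposure"], 99)), 60)

    for outcome in config.outcomes:
        o_res: dict = {}
        y = cohort[f"outcome_{outcome}"].to_numpy(float)
        t0 = time.time()

        # --- observational stage ---
        try:
            obs_cov = cohort[config.observational_covariates]
            best = observational.fit_fp_logistic(
                y, cohort["exposure"].to_numpy(float), obs_cov,
                degree=config.fp_degree, offset=config.fp_offset)
            lin = observational.fit_linear_logistic(
                y, cohort["exposure"].to_numpy(float), obs_cov,
                offset=config.fp_offset)
            stat, df, p = observational.lrt_nonlinearity(
                best, lin, convention=config.df_convention)
            curve = observational.shape_curve(best, grid, config.reference)
            curve.to_frame().to_csv(out / f"observational_curve_{outcome}.tsv",
                                    sep="\t", index=False)
            o_res["observational"] = {
                "powers": list(best.powers), "deviance": best.deviance,
                "lrt_stat": stat, "lrt_df": df, "p_nonlinearity": p,
            }
        except StratMRError as err:
            bundle["errors"][f"observational/{outcome}"] = str(err)

        # --- linear MR stage ---
        try:
            assoc = linear.grs_associations(cohort, grs_arr, outcome,
                                            covariates=config.mr_covariates)
            ratio = linear.ratio_estimate(assoc.beta_zy, assoc.se_zy,
                                          assoc.beta_zx, assoc.se_zx)
            ests = [ratio]
            if stats is not None:
                ests += linear.all_summary_estimates(
                    stats, n_boot=config.n_boot, n_sim=config.n_sim,
                    bandwidth_factor=config.bandwidth_factor,
                    alpha_outlier=config.alpha_outlier, seed=seed)
            o_res["linear_mr"] = [e.to_dict() for e in ests]
        except StratMRError as err:
            bundle["errors"][f"linear_mr/{outcome}"] = str(err)

        # --- non-linear MR stage ---
        try:
            assign = nonlinear.doubly_ranked_strata(
                grs_arr, cohort["exposure"].to_numpy(float),
                config.k_strata, seed=seed)
            strata, dropped = nonlinear.stratum_estimates(
                cohort, assign, grs_arr, outcome,
                covariates=config.mr_covariates,
                min_stratum_size=config.min_stratum_size)
            fit = nonlinear.lace_meta_regression(
                strata, reference=config.reference, offset=config.fp_offset,
                df_convention=("royston" if config.df_convention == "royston"
                               else "coef"))
            mr_curve = nonlinear.nonlinear_report(fit, grid)
            nonlinear.strata_table(strata).to_csv(
                out / f"strata_{outcome}.tsv", sep="\t", index=False)
            mr_curve.to_frame().to_csv(out / f"mr_curve_{outcome}.tsv",
                                       sep="\t", index=False)
            o_res["nonlinear_mr"] = {
                "power": fit.power, "p_nonlinearity": fit.p_nonlinearity,
                "stat": fit.stat_nonlinearity, "df": fit.df,
                "Q": fit.q_statistic, "q_p": fit.q_p,
                "trend_p": fit.trend_p,
                "n_strata_used": len(strata), "dropped": dropped,
            }
        except StratMRError as err:
            bundle["errors"][f"nonlinear_mr/{outcome}"] = str(err)

        bundle["outcomes"][outcome] = o_res
        log.info("outcome %s done (%.1fs)", outcome, time.time() - t0)

    bundle_path = out / "bundle.json"
    with open(bundle_path, "w") as fh:
        json.dump(bundle, fh, indent=2, default=float)

    resolved = config.to_dict()
    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": seed,
        "config": resolved,
        "config_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "files": {p.name: _sha256(p) for p in files},
        "versions": {"stratmr": __import__("stratmr").__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle


def render_report(bundle_dir: str | Path) -> list[Path]:
    """Render per-outcome figures and a text summary from a bundle.

    Missing stages are flagged rather than fatal.  Returns the paths
    written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(bundle_dir)
    with open(out / "bundle.json") as fh:
        bundle = json.load(fh)
    if not bundle.get("outcomes"):
        raise InvalidParameterError("bundle contains no outcomes")

    written: list[Path] = []
    lines = ["stratmr report", "=" * 40]
    for outcome, res in bundle["outcomes"].items():
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        fig.suptitle(f"Outcome: {outcome}")

        ax = axes[0]
        obs_path = out / f"observational_curve_{outcome}.tsv"
        if obs_path.exists() and "observational" in res:
            d = pd.read_csv(obs_path, sep="\t")
            ax.plot(d["x"], d["or"], color="C0")
            ax.fill_between(d["x"], d["ci_low"], d["ci_high"], alpha=0.25)
            ax.axhline(1.0, ls=":", color="grey")
            ax.plot([8.0], [1.0], "o", color="black")
            ax.set_title("Observational (FP fit), "
                         f"p_nl={res['observational']['p_nonlinearity']:.3g}")
        else:
            ax.set_title("observational stage missing")
        ax.set_xlabel("alcohol (g/day)")
        ax.set_ylabel("OR vs 8 g/day")

        ax = axes[1]
        if "linear_mr" in res:
            rows = res["linear_mr"]
            ors = [r["or_per_unit"] for r in rows]
            los = [r["or_ci_low"] for r in rows]
            his = [r["or_ci_high"] for r in rows]
            names = [r["method"] for r in rows]
            ypos = np.arange(len(rows))[::-1]
            ax.errorbar(ors, ypos,
                        xerr=[np.array(ors) - np.array(los),
                              np.array(his) - np.array(ors)],
                        fmt="s", color="C1")
            ax.set_yticks(ypos, names)
            ax.axvline(1.0, ls=":", color="grey")
            ax.set_title("Linear MR, OR per 8 g/day")
        else:
            ax.set_title("linear MR stage missing")

        ax = axes[2]
        mr_path = out / f"mr_curve_{outcome}.tsv"
        if mr_path.exists() and "nonlinear_mr" in res:
            d = pd.read_csv(mr_path, sep="\t")
            ax.plot(d["x"], d["or"], color="C2")
            ax.fill_between(d["x"], d["ci_low"], d["ci_high"], alpha=0.25)
            ax.axhline(1.0, ls=":", color="grey")
            ax.plot([8.0], [1.0], "o", color="black")
            ax.set_title("Non-linear MR, "
                         f"p_nl={res['nonlinear_mr']['p_nonlinearity']:.3g}")
        else:
            ax.set_title("non-linear MR stage missing")
        ax.set_xlabel("alcohol (g/day)")

        fig.tight_layout()
        fig_path = out / f"report_{outcome}.png"
        fig.savefig(fig_path, dpi=110)
        plt.close(fig)
        written.append(fig_path)

        lines.append(f"\n[{outcome}]")
        if "observational" in res:
            lines.append(
                f"  observational p_nonlinearity = "
                f"{res['observational']['p_nonlinearity']:.4g}")
        if "linear_mr" in res:
            for r in res["linear_mr"]:
                lines.append(
                    f"  {r['method']:>16s}: OR/8g = {r['or_per_unit']:.3f} "
                    f"({r['or_ci_low']:.3f}-{r['or_ci_high']:.3f})")
        if "nonlinear_mr" in res:
            lines.append(
                f"  non-linear MR p_nonlinearity = "
                f"{res['nonlinear_mr']['p_nonlinearity']:.4g} "
                f"(power {res['nonlinear_mr']['power']})")
    for key, msg in bundle.get("errors", {}).items():
        lines.append(f"  MISSING {key}: {msg}")

    txt = out / "report.txt"
    txt.write_text("\n".join(lines) + "\n")
    written.append(txt)
    return written
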