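"""End-to-end analysis: filter -> fit -> effect sizes -> meta-regressions
-> species estimates -> rate-capacity correlation.

The pipeline reproduces the two-stage design of the acclimation
meta-analysis: per-experiment nonlinear fits give rate (lambda) and
capacity (ARR) effect sizes with known sampling variances; two univariate
multilevel meta-regressions (AICc-selected moderators, REML reporting)
give species-level estimates via BLUPs; and the headline question —
whether species that acclimate fast acclimate little — is answered by the
correlation between the standardized species-level rate and capacity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .effects import build_effects
from .metareg import MetaRegressionResults, model_select, pseudo_r2
from .metareg import MetaRegression
from .simulate import (ExperimentDatabase, SimConfig, read_database,
                       simulate_database, write_database)
from .timecourse import fit_database

__all__ = [
    "SpeciesEstimate",
    "CorrelationReport",
    "PipelineResult",
    "filter_experiments",
    "species_estimates",
    "correlate",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: acclimation temperature (°C) to which species-level rates are standardized
STANDARD_TEMP_C = 20.0


@dataclass(frozen=True)
class SpeciesEstimate:
    """Species-level rate (at 20 °C, CTmax) and capacity (CTmax) estimates."""

    species: str
    lambda_20: float
    arr_ctmax: float


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson and Spearman rate-capacity correlations across species."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n_species: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def filter_experiments(db: ExperimentDatabase):
    """Apply the eligibility rules and log what each one removed.

    In order: drop time-to-death (TTD) endpoint experiments, whose scale is
    incommensurable with critical temperatures; drop experiments with fewer
    than three timepoints after the baseline (two parameters cannot be
    identified from fewer); drop experiments missing either acclimation
    temperature (the ARR needs both).
    """
    frame = db.frame
    per_exp = frame.groupby("experiment_id", sort=False)
    reasons: dict[str, str] = {}
    for eid, g in per_exp:
        if str(g["trait_type"].iloc[0]).upper() == "TTD":
            reasons[eid] = "ttd_endpoint"
        elif int((g["time_h"] > 0).sum()) < 3:
            reasons[eid] = "lt3_post_baseline"
        elif g["initial_temp_C"].isna().any() or g["acclim_temp_C"].isna().any():
            reasons[eid] = "missing_temperature"
    keep = [eid for eid in db.experiment_ids if eid not in reasons]
    log = {
        "n_input": db.n_experiments,
        "n_retained": len(keep),
        "excluded": {
            reason: sorted(e for e, r in reasons.items() if r == reason)
            for reason in ("ttd_endpoint", "lt3_post_baseline",
                           "missing_temperature")
        },
    }
    log["n_excluded"] = {k: len(v) for k, v in log["excluded"].items()}
    if not keep:
        raise ValueError("no experiments left after filtering")
    for reason, ids in log["excluded"].items():
        for eid in ids:
            logger.info("excluding %s: %s", eid, reason)
    return db.subset(keep), log


def species_estimates(rate_results: MetaRegressionResults,
                      arr_results: MetaRegressionResults) -> pd.DataFrame:
    """Per-species standardized estimates from the two fitted models.

    The rate is the conditional (fixed + BLUP) prediction for a CTmax
    trait at 20 °C; the capacity is the conditional CTmax prediction from
    the ARR model (temperature never enters the capacity model here unless
    it was selected, in which case it is still evaluated at 20 °C).
    """
    blup_rate = rate_results.blup()
    blup_arr = arr_results.blup()
    shared = blup_rate.index.intersection(blup_arr.index)
    if shared.empty:
        raise ValueError("rate and capacity models share no species")
    dropped = set(blup_rate.index).symmetric_difference(blup_arr.index)
    if dropped:
        warnings.warn(f"{len(dropped)} species present in only one model "
                      f"dropped: {sorted(dropped)}", stacklevel=2)

    def _fixed(res):
        needs_temp = "acclim_temp" in res.model.moderators
        return res.predict(acclim_temp_C=STANDARD_TEMP_C if needs_temp else None,
                           trait_type="CTmax")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 20 °C may sit outside a tiny sim range
        fr = _fixed(rate_results)
        fa = _fixed(arr_results)
    out = pd.DataFrame({
        "species": shared,
        "lambda_20": fr + blup_rate.loc[shared].to_numpy(),
        "arr_ctmax": fa + blup_arr.loc[shared].to_numpy(),
    })
    if not np.all(np.isfinite(out[["lambda_20", "arr_ctmax"]])):
        raise ValueError("non-finite species estimates")
    return out.reset_index(drop=True)


def correlate(est: pd.DataFrame) -> CorrelationReport:
    """Pearson and Spearman correlation between species rate and capacity.

    Two-sided p-values from the t-approximation on n-2 degrees of freedom
    (Spearman: the same approximation applied to rank-transformed data,
    average ranks for ties).
    """
    x = est["lambda_20"].to_numpy(float)
    y = est["arr_ctmax"].to_numpy(float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 species to correlate")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in species estimates")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationReport(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        n_species=int(n),
    )


# ----------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything the pipeline produced, in memory."""

    database: ExperimentDatabase
    exclusion_log: dict
    fits: pd.DataFrame
    effects: pd.DataFrame
    rate_results: MetaRegressionResults
    rate_aicc_table: pd.DataFrame
    arr_results: MetaRegressionResults
    arr_aicc_table: pd.DataFrame
    rate_pseudo_r2: float
    arr_pseudo_r2: float
    estimates: pd.DataFrame
    correlation: CorrelationReport
    manifest: dict


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: dict, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis from a config mapping.

    Config keys: either ``database`` (path to a long-format CSV) or
    ``simulate`` (SimConfig fields); plus optional ``variance_mode``
    (default ``paper_literal``), ``n_starts`` (default 10) and ``seed``
    (default 0).  When ``outdir`` is given, all tabular outputs, model
    reports and a run manifest are written there.
    """
    variance_mode = config.get("variance_mode", "paper_literal")
    n_starts = int(config.get("n_starts", 10))
    seed = int(config.get("seed", 0))

    if "database" in config:
        db = read_database(config["database"])
        source = str(config["database"])
    elif "simulate" in config:
        sim_cfg = SimConfig.from_dict({**config["simulate"]})
        db, _ = simulate_database(sim_cfg)
        source = "simulated"
    else:
        raise ValueError("config must name a 'database' CSV or a 'simulate' block")

    db_f, exclusion_log = filter_experiments(db)
    logger.info("stage filter: %d -> %d experiments", exclusion_log["n_input"],
                exclusion_log["n_retained"])

    fits = fit_database(db_f, n_starts=n_starts, seed=seed)
    n_conv = int(fits["converged"].sum())
    logger.info("stage fit: %d/%d converged", n_conv, len(fits))

    effects = build_effects(fits, variance_mode=variance_mode)
    if effects.empty:
        raise ValueError("stage effects: no converged experiments")

    rate_eff = effects[effects["measure"] == "rate"].reset_index(drop=True)
    arr_eff = effects[effects["measure"] == "capacity"].reset_index(drop=True)

    rate_best, rate_table = model_select(rate_eff)
    arr_best, arr_table = model_select(arr_eff)
    logger.info("stage metareg: rate moderators=%s, capacity moderators=%s",
                rate_best.model.moderators, arr_best.model.moderators)

    rate_null = MetaRegression.from_effects(rate_eff, ()).fit("REML")
    arr_null = MetaRegression.from_effects(arr_eff, ()).fit("REML")
    rate_r2 = pseudo_r2(rate_best, rate_null)
    arr_r2 = pseudo_r2(arr_best, arr_null)

    est = species_estimates(rate_best, arr_best)
    report = correlate(est)
    logger.info("stage correlate: pearson r=%.3f (p=%.4f), spearman rho=%.3f "
                "(p=%.4f), n=%d", report.pearson_r, report.pearson_p,
                report.spearman_rho, report.spearman_p, report.n_species)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "n_starts": n_starts,
        "variance_mode": variance_mode,
        "database_source": source,
        "n_experiments_input": exclusion_log["n_input"],
        "n_experiments_retained": exclusion_log["n_retained"],
        "n_experiments_converged": n_conv,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    result = PipelineResult(
        database=db_f, exclusion_log=exclusion_log, fits=fits, effects=effects,
        rate_results=rate_best, rate_aicc_table=rate_table,
        arr_results=arr_best, arr_aicc_table=arr_table,
        rate_pseudo_r2=rate_r2, arr_pseudo_r2=arr_r2,
        estimates=est, correlation=report, manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _model_report(res: MetaRegressionResults, table: pd.DataFrame,
                  r2: float) -> dict:
    return {**res.to_dict(), "pseudo_r2": r2,
            "aicc_table": table.to_dict(orient="records")}


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(outdir / "fits.csv", index=False)
    result.effects.to_csv(outdir / "effects.csv", index=False)
    result.estimates.to_csv(outdir / "species_estimates.csv", index=False)
    (outdir / "rate_model.json").write_text(json.dumps(
        _model_report(result.rate_results, result.rate_aicc_table,
                      result.rate_pseudo_r2), indent=1))
    (outdir / "capacity_model.json").write_text(json.dumps(
        _model_report(result.arr_results, result.arr_aicc_table,
                      result.arr_pseudo_r2), indent=1))
    (outdir / "correlation.json").write_text(
        json.dumps(result.correlation.to_dict(), indent=1))
    (outdir / "exclusions.json").write_text(
        json.dumps(result.exclusion_log, indent=1))
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1))


def plot_species_estimates(est: pd.DataFrame, ax=None):
    """Convenience scatter of species-level capacity against rate."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(est["lambda_20"], est["arr_ctmax"], s=18, alpha=0.7)
    ax.set_xlabel("plasticity rate λ at 20 °C (h$^{-1}$)")
    ax.set_ylabel("plasticity capacity ARR, CTmax (°C °C$^{-1}$)")
    return ax
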