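"""Meta-analysis-ready effect sizes from per-experiment fits.

Each converged fit yields two observations: the rate effect (lambda with
its sampling variance) and the capacity effect, expressed as an
acclimation response ratio ARR = |Z_inf / dT| where dT is the difference
between the new and initial acclimation temperatures.  Two conventions for
the ARR sampling variance are supported: ``paper_literal`` divides
var(Z_inf) by |dT| (the wording of the source analysis, dimensionally
inconsistent but reproduced as written) and ``delta_method`` divides by
dT^2 (the first-order variance of Z_inf/dT).  Neither is silently
preferred; the mode travels with every output row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .timecourse import AcclimationFit

__all__ = ["EffectSize", "to_arr", "to_rate_effect", "build_effects",
           "VARIANCE_MODES"]

logger = logging.getLogger(__name__)

VARIANCE_MODES = ("paper_literal", "delta_method")


@dataclass(frozen=True)
class EffectSize:
    """One meta-analytic observation: a value, its sampling variance, moderators."""

    experiment_id: str
    species: str
    study_id: str
    trait_type: str
    acclim_temp_C: float
    value: float
    sampling_var: float
    measure: str  # "rate" or "capacity"

    def __post_init__(self) -> None:
        if self.sampling_var < 0:
            raise ValueError("sampling_var must be >= 0")
        if self.measure not in ("rate", "capacity"):
            raise ValueError("measure must be 'rate' or 'capacity'")


def to_arr(fit: AcclimationFit, initial_temp_C: float, acclim_temp_C: float,
           variance_mode: str = "paper_literal", *, experiment_id: str = "",
           species: str = "", study_id: str = "",
           trait_type: str = "") -> EffectSize:
    """Convert a capacity estimate to an acclimation response ratio.

    ARR = |Z_inf / dT| with dT = acclim_temp_C - initial_temp_C.
    """
    if not fit.converged:
        raise ValueError("cannot compute ARR from a non-converged fit")
    if variance_mode not in VARIANCE_MODES:
        raise ValueError(f"variance_mode must be one of {VARIANCE_MODES}")
    dt = acclim_temp_C - initial_temp_C
    if dt == 0:
        raise ValueError("ARR undefined: acclimation and initial temperature equal")
    value = abs(fit.Z_inf_hat / dt)
    if variance_mode == "paper_literal":
        var = fit.var_Z_inf / abs(dt)
    else:
        var = fit.var_Z_inf / dt**2
    return EffectSize(
        experiment_id=experiment_id, species=species, study_id=study_id,
        trait_type=trait_type, acclim_temp_C=acclim_temp_C,
        value=value, sampling_var=var, measure="capacity",
    )


def to_rate_effect(fit: AcclimationFit, *, experiment_id: str = "",
                   species: str = "", study_id: str = "", trait_type: str = "",
                   acclim_temp_C: float = float("nan")) -> EffectSize:
    """Pass a converged rate estimate through as an effect size."""
    if not fit.converged:
        raise ValueError("cannot build a rate effect from a non-converged fit")
    return EffectSize(
        experiment_id=experiment_id, species=species, study_id=study_id,
        trait_type=trait_type, acclim_temp_C=acclim_temp_C,
        value=fit.lambda_hat, sampling_var=fit.var_lambda, measure="rate",
    )


def build_effects(fits: pd.DataFrame,
                  variance_mode: str = "paper_literal") -> pd.DataFrame:
    """Assemble rate and capacity effect sizes from a fit-results table.

    Non-converged experiments are excluded with a logged reason; every
    converged experiment contributes exactly one rate and one capacity row.
    """
    if variance_mode not in VARIANCE_MODES:
        raise ValueError(f"variance_mode must be one of {VARIANCE_MODES}")
    rows = []
    for rec in fits.to_dict(orient="records"):
        if not rec["converged"]:
            logger.info("excluding %s: fit did not converge", rec["experiment_id"])
            continue
        fit = AcclimationFit(
            Z_inf_hat=rec["Z_inf_hat"], lambda_hat=rec["lambda_hat"],
            var_Z_inf=rec["var_Z_inf"], var_lambda=rec["var_lambda"],
            cov=rec["cov"], rss=rec["rss"], n_points=rec["n_points"],
            converged=True, n_starts_converged=rec["n_starts_converged"],
        )
        meta = dict(experiment_id=rec["experiment_id"], species=rec["species"],
                    study_id=rec["study_id"], trait_type=rec["trait_type"],
                    acclim_temp_C=rec["acclim_temp_C"])
        rate = to_rate_effect(fit, **meta)
        cap = to_arr(fit, rec["initial_temp_C"], rec["acclim_temp_C"],
                     variance_mode,
                     **{k: v for k, v in meta.items() if k != "acclim_temp_C"})
        for e in (rate, cap):
            rows.append({**e.__dict__, "variance_mode": variance_mode})
    out = pd.DataFrame(rows, columns=[
        "experiment_id", "species", "study_id", "trait_type", "acclim_temp_C",
        "value", "sampling_var", "measure", "variance_mode",
    ])
    return out
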