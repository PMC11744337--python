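"""Multilevel random-effects meta-regression with known sampling variances.

The model for effect size :math:`y_i` (a per-experiment rate or ARR
estimate) is

.. math::

    y_i = x_i^T \\beta + u_{species(i)} + w_i + \\varepsilon_i,

with a species-level random intercept :math:`u_s \\sim N(0, \\tau^2)`,
experiment-level heterogeneity :math:`w_i \\sim N(0, \\gamma^2)` and known
sampling error :math:`\\varepsilon_i \\sim N(0, v_i)`.  The marginal
covariance is :math:`V = \\tau^2 Z_s Z_s^T + \\gamma^2 I + diag(v)`; the
variance components are estimated by ML or REML with the fixed effects
profiled out (GLS), moderators are compared by AICc under ML, and
species-level intercepts are recovered as BLUPs.  A study-level random
effect is deliberately not modelled: in the acclimation literature most
studies contribute a single species, which makes study and species
variance inseparable.  Phylogenetic species effects are likewise not
estimated here; the relatedness diagnostic lives in :mod:`acclim.phylo`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetaSpec",
    "MetaRegression",
    "MetaRegressionResults",
    "predict_from_coefficients",
    "aicc",
    "model_select",
    "heterogeneity",
    "pseudo_r2",
]

logger = logging.getLogger(__name__)

MODERATORS = ("acclim_temp", "trait_type")
DEFAULT_CANDIDATES = ((), ("acclim_temp",), ("trait_type",),
                      ("acclim_temp", "trait_type"))
_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MetaSpec:
    """Which moderators enter the fixed part and how the fit is estimated.

    The random structure is fixed: a species intercept and experiment-level
    residual heterogeneity are always present.
    """

    moderators: tuple[str, ...] = ()
    method: str = "REML"

    def __post_init__(self) -> None:
        bad = set(self.moderators) - set(MODERATORS)
        if bad:
            raise ValueError(f"unknown moderators: {sorted(bad)}")
        if self.method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank == X.shape[1]:
        return []
    # crude but informative: report columns whose removal restores full rank
    bad = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
            bad.append(names[j])
    return bad or names


class MetaRegression:
    """Multilevel random-effects meta-regression model.

    Parameters
    ----------
    y : array
        Effect sizes (lambda in h^-1 or ARR in °C °C^-1).
    v : array
        Known sampling variances of ``y`` (same units squared).
    species : array of str
        Species label per effect; defines the random-intercept grouping.
    X : 2-D array, optional
        Fixed-effect design matrix.  Defaults to an intercept-only column.
    exog_names : list of str, optional
        Column labels for ``X``.
    """

    def __init__(self, y, v, species, X=None, exog_names=None):
        self.y = np.asarray(y, float)
        self.v = np.asarray(v, float)
        n = self.y.size
        if self.v.size != n:
            raise ValueError("y and v must have the same length")
        if np.any(self.v < 0) or not np.all(np.isfinite(self.v)):
            raise ValueError("sampling variances must be finite and >= 0")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("effect sizes must be finite")
        self.species = np.asarray(species, dtype=object)
        if self.species.size != n:
            raise ValueError("species labels must match y in length")
        self.species_levels, self._sp_idx = np.unique(self.species,
                                                      return_inverse=True)
        if self.species_levels.size < 2:
            raise ValueError("need effects from at least 2 species")
        if X is None:
            X = np.ones((n, 1))
            exog_names = ["intercept"]
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] != n:
            raise ValueError("X must be n x p")
        self.exog_names = list(exog_names) if exog_names is not None else \
            [f"x{j}" for j in range(X.shape[1])]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            bad = _collinear_columns(X, self.exog_names)
            raise ValueError(f"design matrix is rank deficient; collinear "
                             f"column(s): {bad}")
        self.X = X
        self.nobs = n
        self.k_exog = X.shape[1]
        # species indicator matrix (n x S) and its Gram matrix, reused in
        # every likelihood evaluation
        self.Z = np.zeros((n, self.species_levels.size))
        self.Z[np.arange(n), self._sp_idx] = 1.0
        self._ZZt = self.Z @ self.Z.T
        self.moderators: tuple[str, ...] = ()
        self._temp_range: tuple[float, float] | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_effects(cls, effects: pd.DataFrame,
                     moderators: tuple[str, ...] = ()) -> "MetaRegression":
        """Build a model from an effects table (one measure at a time).

        ``moderators`` may include ``"acclim_temp"`` (the new acclimation
        temperature, °C, as a linear term) and ``"trait_type"`` (a CTmin
        dummy, so the intercept is the CTmax level).
        """
        if effects["measure"].nunique() > 1:
            raise ValueError("effects table mixes measures; fit one at a time")
        cols = [np.ones(len(effects))]
        names = ["intercept"]
        if "acclim_temp" in moderators:
            cols.append(effects["acclim_temp_C"].to_numpy(float))
            names.append("acclim_temp")
        if "trait_type" in moderators:
            cols.append((effects["trait_type"] == "CTmin").to_numpy(float))
            names.append("trait_ctmin")
        model = cls(effects["value"].to_numpy(float),
                    effects["sampling_var"].to_numpy(float),
                    effects["species"].to_numpy(), np.column_stack(cols), names)
        model.moderators = tuple(m for m in MODERATORS if m in moderators)
        t = effects["acclim_temp_C"].to_numpy(float)
        if np.all(np.isfinite(t)):
            model._temp_range = (float(t.min()), float(t.max()))
        return model

    # ------------------------------------------------------------------
    def _marginal_cov(self, tau2: float, gamma2: float) -> np.ndarray:
        V = tau2 * self._ZZt
        V[np.diag_indices_from(V)] += gamma2 + self.v
        return V

    def _profile(self, tau2: float, gamma2: float):
        """GLS quantities at fixed variance components (via Cholesky)."""
        from scipy.linalg import cho_factor, cho_solve
        V = self._marginal_cov(tau2, gamma2)
        c, low = cho_factor(V, lower=True)
        logdetV = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv_X = cho_solve((c, low), self.X)
        Vinv_y = cho_solve((c, low), self.y)
        XtVinvX = self.X.T @ Vinv_X
        beta = np.linalg.solve(XtVinvX, self.X.T @ Vinv_y)
        r = self.y - self.X @ beta
        Vinv_r = cho_solve((c, low), r)
        quad = float(r @ Vinv_r)
        return beta, XtVinvX, logdetV, quad, (c, low)

    def loglike(self, tau2: float, gamma2: float, method: str = "REML") -> float:
        """Profiled (in beta) ML or REML log-likelihood at (tau2, gamma2)."""
        n, p = self.nobs, self.k_exog
        try:
            beta, XtVinvX, logdetV, quad, _ = self._profile(tau2, gamma2)
        except np.linalg.LinAlgError:
            return -np.inf
        if method == "ML":
            return -0.5 * (n * np.log(2 * np.pi) + logdetV + quad)
        sign, logdetXtVinvX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return -np.inf
        # the +log|X'X|/2 constant makes this the exact log-density of the
        # error contrasts A'y (A an orthonormal complement of X)
        _, logdetXtX = np.linalg.slogdet(self.X.T @ self.X)
        return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV
                       + logdetXtVinvX + quad - logdetXtX)

    def _start_points(self) -> list[np.ndarray]:
        # method-of-moments scale for the total heterogeneity
        beta_ols, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta_ols
        s2 = max(float(np.var(resid, ddof=min(self.k_exog, resid.size - 1)))
                 - float(np.mean(self.v)), 1e-4 * float(np.var(self.y) + 1e-12))
        return [np.array(p) for p in (
            (0.5 * s2, 0.5 * s2),
            (0.95 * s2, 0.05 * s2),
            (0.05 * s2, 0.95 * s2),
        )]

    def fit(self, method: str = "REML") -> "MetaRegressionResults":
        """Estimate (tau2, gamma2) by box-constrained quasi-Newton, beta by GLS."""
        if method not in ("ML", "REML"):
            raise ValueError("method must be 'ML' or 'REML'")

        def nll(theta):
            ll = self.loglike(theta[0], theta[1], method)
            return -ll if np.isfinite(ll) else 1e12

        best = None
        n_ok = 0
        for x0 in self._start_points():
            res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                    bounds=[(0.0, None), (0.0, None)])
            if not np.isfinite(res.fun):
                continue
            n_ok += 1
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        converged = best is not None and n_ok > 0
        if not converged:
            raise RuntimeError("variance-component optimization did not converge")
        tau2, gamma2 = (max(float(t), 0.0) for t in best.x)
        beta, XtVinvX, _, _, _ = self._profile(tau2, gamma2)
        cov_beta = np.linalg.inv(XtVinvX)
        ll = self.loglike(tau2, gamma2, method)
        return MetaRegressionResults(
            model=self, method=method, beta=beta, cov_beta=cov_beta,
            tau2_species=tau2, gamma2_exp=gamma2, llf=float(ll),
            converged=bool(best.success),
        )


@dataclass
class MetaRegressionResults:
    """Fitted meta-regression: coefficients, variance components, diagnostics."""

    model: MetaRegression
    method: str
    beta: np.ndarray
    cov_beta: np.ndarray
    tau2_species: float
    gamma2_exp: float
    llf: float
    converged: bool

    # ------------------------------------------------------------------
    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.beta - z * self.bse,
                                self.beta + z * self.bse])

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_species(self) -> int:
        return int(self.model.species_levels.size)

    # ------------------------------------------------------------------
    def aicc(self) -> float:
        """Corrected AIC; requires an ML fit.

        The parameter count includes the two variance components
        (p = #fixed effects + 2), the convention used by common
        meta-analytic software.
        """
        if self.method != "ML":
            raise ValueError("AICc is defined here for ML fits; refit with ML")
        p = self.model.k_exog + 2
        n = self.nobs
        if n <= p + 1:
            raise ValueError("AICc correction undefined: n <= p + 1")
        return float(-2.0 * self.llf + 2 * p + 2 * p * (p + 1) / (n - p - 1))

    def heterogeneity(self) -> dict:
        """Multilevel I² split across species and experiment levels.

        Uses the Higgins–Thompson 'typical' sampling variance
        ṽ = (n−1)Σw / ((Σw)² − Σw²) with w_i = 1/v_i.
        """
        v = self.model.v
        pos = v > 0
        if not np.all(pos):
            warnings.warn("zero sampling variances present; typical sampling "
                          "variance computed over positive-variance effects",
                          stacklevel=2)
        w = 1.0 / v[pos]
        n = w.size
        vtilde = (n - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
        total = self.tau2_species + self.gamma2_exp + vtilde
        i2_sp = 100.0 * self.tau2_species / total
        i2_exp = 100.0 * self.gamma2_exp / total
        return {"i2_species": float(i2_sp), "i2_exp": float(i2_exp),
                "i2_total": float(i2_sp + i2_exp),
                "typical_sampling_var": float(vtilde)}

    def blup(self) -> pd.Series:
        """Best linear unbiased predictions of the species intercepts.

        û = τ² Z_s' V⁻¹ (y − Xβ̂); species with more, lower-variance effects
        shrink less.  With τ² = 0 every prediction is exactly 0.
        """
        m = self.model
        if self.tau2_species == 0.0:
            logger.info("tau2 = 0: all species BLUPs are 0")
            u = np.zeros(m.species_levels.size)
        else:
            V = m._marginal_cov(self.tau2_species, self.gamma2_exp)
            r = m.y - m.X @ self.beta
            u = self.tau2_species * (m.Z.T @ np.linalg.solve(V, r))
        return pd.Series(u, index=pd.Index(m.species_levels, name="species"),
                         name="blup")

    def predict(self, acclim_temp_C: float | None = None,
                trait_type: str = "CTmax") -> float:
        """Fixed-effect prediction at the given covariates."""
        if trait_type not in ("CTmax", "CTmin"):
            raise ValueError(f"unknown trait_type level: {trait_type!r}")
        x = []
        for name in self.model.exog_names:
            if name == "intercept":
                x.append(1.0)
            elif name == "acclim_temp":
                if acclim_temp_C is None:
                    raise ValueError("model includes acclim_temp; a temperature "
                                     "is required")
                tr = self.model._temp_range
                if tr is not None and not (tr[0] <= acclim_temp_C <= tr[1]):
                    warnings.warn(
                        f"acclimation temperature {acclim_temp_C} °C is outside "
                        f"the fitted range {tr}; extrapolating", stacklevel=2)
                x.append(float(acclim_temp_C))
            elif name == "trait_ctmin":
                x.append(1.0 if trait_type == "CTmin" else 0.0)
            else:  # pragma: no cover - no other columns are constructed
                raise ValueError(f"cannot build covariate for column {name!r}")
        return float(np.asarray(x) @ self.beta)

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "method": self.method,
            "moderators": list(self.model.moderators),
            "n_effects": self.nobs,
            "n_species": self.n_species,
            "converged": self.converged,
            "loglik": self.llf,
            "beta": [
                {"name": nm, "estimate": float(b), "se": float(s),
                 "ci_lower": float(lo), "ci_upper": float(hi)}
                for nm, b, s, (lo, hi) in zip(self.model.exog_names, self.beta,
                                              self.bse, ci)
            ],
            "tau2_species": self.tau2_species,
            "gamma2_exp": self.gamma2_exp,
            "heterogeneity": self.heterogeneity(),
            "blups": {str(k): float(v) for k, v in self.blup().items()},
        }

    def summary(self) -> str:
        ci = self.conf_int()
        het = self.heterogeneity()
        lines = [
            "Multilevel random-effects meta-regression",
            "=========================================",
            f"method: {self.method}   n effects: {self.nobs}   "
            f"species: {self.n_species}   loglik: {self.llf:.3f}",
            "",
            f"{'coef':<14}{'estimate':>12}{'se':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        for nm, b, s, (lo, hi) in zip(self.model.exog_names, self.beta,
                                      self.bse, ci):
            lines.append(f"{nm:<14}{b:>12.5f}{s:>12.5f}{lo:>12.5f}{hi:>12.5f}")
        lines += [
            "",
            f"tau2 (species)    {self.tau2_species:.6g}",
            f"gamma2 (experiment) {self.gamma2_exp:.6g}",
            f"I2 species/exp/total: {het['i2_species']:.1f} / "
            f"{het['i2_exp']:.1f} / {het['i2_total']:.1f} %",
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
# module-level conveniences mirroring the analysis workflow


def predict_from_coefficients(coef: dict, acclim_temp_C: float = 0.0,
                              trait_type: str = "CTmax") -> float:
    """Linear prediction from a printed coefficient table.

    ``coef`` maps ``intercept``, optionally ``acclim_temp`` (per °C) and
    ``trait_ctmin`` (the CTmin offset; the intercept is the CTmax level).
    """
    if trait_type not in ("CTmax", "CTmin"):
        raise ValueError(f"unknown trait_type level: {trait_type!r}")
    out = float(coef["intercept"])
    if "acclim_temp" in coef:
        out += float(coef["acclim_temp"]) * acclim_temp_C
    if trait_type == "CTmin" and "trait_ctmin" in coef:
        out += float(coef["trait_ctmin"])
    return out


def aicc(results: MetaRegressionResults) -> float:
    """Corrected AIC of an ML-fitted model (see ``MetaRegressionResults.aicc``)."""
    return results.aicc()


def model_select(effects: pd.DataFrame,
                 candidates=DEFAULT_CANDIDATES):
    """AICc model selection over moderator sets; winner refit by REML.

    All candidates are fit by maximum likelihood, compared by AICc, and the
    lowest-AICc model is refit by REML for reporting.  Returns
    ``(best_results_reml, table)`` where the table lists every candidate's
    AICc (non-convergent candidates are recorded and excluded from the
    comparison with a warning).
    """
    rows = []
    fits = {}
    for mods in candidates:
        mods = tuple(mods)
        try:
            res = MetaRegression.from_effects(effects, mods).fit(method="ML")
            rows.append({"moderators": "+".join(mods) or "(intercept only)",
                         "aicc": res.aicc(), "loglik": res.llf,
                         "converged": True})
            fits[mods] = res
        except (RuntimeError, ValueError) as err:
            warnings.warn(f"candidate {mods or '(intercept only)'} failed: {err}",
                          stacklevel=2)
            rows.append({"moderators": "+".join(mods) or "(intercept only)",
                         "aicc": np.nan, "loglik": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    ok = table["converged"]
    if not ok.any():
        raise RuntimeError("no candidate model converged")
    best_label = table.loc[ok, "aicc"].idxmin()
    best_mods = tuple(c for c in candidates)[best_label]
    best = MetaRegression.from_effects(effects, tuple(best_mods)).fit(method="REML")
    table = table.sort_values("aicc").reset_index(drop=True)
    return best, table


def heterogeneity(results: MetaRegressionResults) -> tuple[float, float, float]:
    """(I²_species, I²_experiment, I²_total) in percent."""
    h = results.heterogeneity()
    return h["i2_species"], h["i2_exp"], h["i2_total"]


def pseudo_r2(full: MetaRegressionResults,
              null: MetaRegressionResults) -> float:
    """Percent reduction in total heterogeneity relative to an intercept-only fit.

    100 * max(0, (τ²₀ + γ²₀ − τ² − γ²) / (τ²₀ + γ²₀)); 0 when the null
    model has no heterogeneity at all.
    """
    if full.nobs != null.nobs or not np.array_equal(full.model.y, null.model.y):
        raise ValueError("pseudo-R² requires both models fit to the same data")
    if null.model.k_exog != 1:
        raise ValueError("null model must be intercept-only")
    denom = null.tau2_species + null.gamma2_exp
    if denom == 0:
        return 0.0
    num = denom - full.tau2_species - full.gamma2_exp
    return float(100.0 * max(0.0, num / denom))
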