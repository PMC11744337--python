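"""Multilevel meta-regression: likelihood, selection, heterogeneity, BLUPs."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import null_space
from scipy.stats import multivariate_normal

from acclim.metareg import (MetaRegression, MetaRegressionResults, MetaSpec,
                            model_select, predict_from_coefficients, pseudo_r2)

from conftest import meta_effects


def _simple_effects(y, v, species, temp=20.0, trait="CTmax"):
    n = len(y)
    return pd.DataFrame({
        "value": y, "sampling_var": v, "species": species,
        "acclim_temp_C": np.full(n, temp), "trait_type": [trait] * n,
        "measure": "rate",
    })


class TestLikelihood:
    def test_ml_matches_direct_mvn_density(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(8, 21))
            eff = meta_effects(rng, n_species=max(2, n // 3), per_species=1).iloc[:n]
            m = MetaRegression.from_effects(eff, ("acclim_temp",))
            tau2, gamma2 = rng.uniform(0, 0.02, 2)
            V = tau2 * (m.Z @ m.Z.T) + np.diag(gamma2 + m.v)
            beta = np.linalg.solve(m.X.T @ np.linalg.solve(V, m.X),
                                   m.X.T @ np.linalg.solve(V, m.y))
            direct = multivariate_normal.logpdf(m.y, m.X @ beta, V)
            assert abs(m.loglike(tau2, gamma2, "ML") - direct) < 1e-8

    def test_reml_matches_error_contrast_density(self):
        rng = np.random.default_rng(2)
        eff = meta_effects(rng, n_species=6, per_species=3)
        m = MetaRegression.from_effects(eff, ("acclim_temp", "trait_type"))
        tau2, gamma2 = 0.004, 0.001
        V = tau2 * (m.Z @ m.Z.T) + np.diag(gamma2 + m.v)
        A = null_space(m.X.T)
        direct = multivariate_normal.logpdf(A.T @ m.y, np.zeros(A.shape[1]),
                                            A.T @ V @ A)
        assert abs(m.loglike(tau2, gamma2, "REML") - direct) < 1e-8

    def test_reml_closed_form_equal_variance(self):
        """One effect per species, equal v: total heterogeneity matches
        max(0, s²_y − v) and the pooled mean is ȳ."""
        rng = np.random.default_rng(3)
        y = rng.normal(0.2, 0.1, 40)
        v = np.full(40, 0.002)
        eff = _simple_effects(y, v, [f"s{i}" for i in range(40)])
        r = MetaRegression.from_effects(eff, ()).fit("REML")
        closed = max(0.0, np.var(y, ddof=1) - 0.002)
        assert abs((r.tau2_species + r.gamma2_exp) - closed) < 1e-6
        assert abs(r.beta[0] - y.mean()) < 1e-6

    def test_fixed_effect_limit(self):
        """Huge sampling variances swamp heterogeneity: variance components
        go to zero and the SE approaches the fixed-effect formula."""
        rng = np.random.default_rng(4)
        v = np.full(30, 50.0)
        y = rng.normal(0.0, 0.05, 30)
        eff = _simple_effects(y, v, [f"s{i % 10}" for i in range(30)])
        r = MetaRegression.from_effects(eff, ()).fit("REML")
        assert r.tau2_species < 1e-3 and r.gamma2_exp < 1e-3
        assert r.bse[0] ** 2 == pytest.approx(1.0 / np.sum(1.0 / v), rel=0.01)

    def test_gls_beta_at_fixed_variances(self):
        rng = np.random.default_rng(5)
        eff = meta_effects(rng, n_species=20, per_species=2)
        m = MetaRegression.from_effects(eff, ("acclim_temp", "trait_type"))
        beta, XtVinvX, *_ = m._profile(0.001, 0.002)
        V = 0.001 * (m.Z @ m.Z.T) + np.diag(0.002 + m.v)
        Vinv = np.linalg.inv(V)
        beta_direct = np.linalg.solve(m.X.T @ Vinv @ m.X, m.X.T @ Vinv @ m.y)
        np.testing.assert_allclose(beta, beta_direct, rtol=1e-10)

    def test_shift_invariance_of_variance_components(self):
        rng = np.random.default_rng(6)
        eff = meta_effects(rng, n_species=30, per_species=3)
        r1 = MetaRegression.from_effects(eff, ()).fit("REML")
        eff2 = eff.copy()
        eff2["value"] = eff2["value"] + 5.0
        r2 = MetaRegression.from_effects(eff2, ()).fit("REML")
        assert r2.tau2_species == pytest.approx(r1.tau2_species, abs=1e-7)
        assert r2.gamma2_exp == pytest.approx(r1.gamma2_exp, abs=1e-7)
        assert r2.beta[0] == pytest.approx(r1.beta[0] + 5.0, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        eff = _simple_effects(np.ones(10) * 0.1, np.full(10, 1e-4),
                              [f"s{i % 5}" for i in range(10)])
        # constant temperature makes intercept + temperature collinear
        with pytest.raises(ValueError, match="rank deficient"):
            MetaRegression.from_effects(eff, ("acclim_temp",))

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="unknown moderators"):
            MetaSpec(moderators=("bodymass",))
        with pytest.raises(ValueError, match="method"):
            MetaSpec(method="PQL")


class TestAicc:
    def test_arithmetic(self):
        """AICc = -2ll + 2p + 2p(p+1)/(n-p-1) with p = #beta + 2."""
        rng = np.random.default_rng(7)
        eff = meta_effects(rng, n_species=65, per_species=3)
        r = MetaRegression.from_effects(eff, ()).fit("ML")
        p, n = 1 + 2, r.nobs
        expected = -2 * r.llf + 2 * p + 2 * p * (p + 1) / (n - p - 1)
        assert r.aicc() == pytest.approx(expected, rel=1e-12)
        # worked instance of the same formula
        assert -2 * 259.05 + 6 + 24 / 191 == pytest.approx(-511.97, abs=0.01)

    def test_requires_ml(self):
        rng = np.random.default_rng(8)
        eff = meta_effects(rng, n_species=10, per_species=2)
        r = MetaRegression.from_effects(eff, ()).fit("REML")
        with pytest.raises(ValueError, match="ML"):
            r.aicc()

    def test_approaches_aic_for_large_n(self):
        rng = np.random.default_rng(9)
        eff = meta_effects(rng, n_species=400, per_species=3)
        r = MetaRegression.from_effects(eff, ()).fit("ML")
        aic = -2 * r.llf + 2 * (r.model.k_exog + 2)
        assert abs(r.aicc() - aic) < 0.05

    def test_small_n_rejected(self):
        rng = np.random.default_rng(10)
        eff = meta_effects(rng, n_species=2, per_species=2)
        r = MetaRegression.from_effects(eff, ()).fit("ML")
        with pytest.raises(ValueError, match="undefined"):
            r.aicc()


class TestHeterogeneity:
    def _results(self, tau2, gamma2, v):
        n = len(v)
        eff = _simple_effects(np.zeros(n), v, [f"s{i}" for i in range(n)])
        m = MetaRegression.from_effects(eff, ())
        return MetaRegressionResults(model=m, method="REML",
                                     beta=np.zeros(1), cov_beta=np.eye(1),
                                     tau2_species=tau2, gamma2_exp=gamma2,
                                     llf=0.0, converged=True)

    def test_zero_heterogeneity(self):
        h = self._results(0.0, 0.0, np.full(10, 0.01)).heterogeneity()
        assert h["i2_total"] == 0.0

    def test_symmetric_thirds(self):
        """tau2 = gamma2 = typical v gives 33.3/33.3/66.7%."""
        v = np.full(12, 0.01)
        h = self._results(0.01, 0.01, v).heterogeneity()
        assert h["i2_species"] == pytest.approx(100 / 3, rel=1e-9)
        assert h["i2_exp"] == pytest.approx(100 / 3, rel=1e-9)
        assert h["i2_total"] == pytest.approx(200 / 3, rel=1e-9)

    def test_equal_v_typical_variance_reduces(self):
        v = np.full(9, 0.004)
        h = self._results(0.001, 0.002, v).heterogeneity()
        assert h["typical_sampling_var"] == pytest.approx(0.004, rel=1e-12)


class TestPseudoR2:
    def test_full_equals_null(self):
        rng = np.random.default_rng(11)
        eff = meta_effects(rng, n_species=20, per_species=2)
        r = MetaRegression.from_effects(eff, ()).fit("REML")
        assert pseudo_r2(r, r) == 0.0

    def test_arithmetic(self):
        rng = np.random.default_rng(12)
        eff = meta_effects(rng, n_species=20, per_species=2)
        m = MetaRegression.from_effects(eff, ())
        mk = lambda t2, g2: MetaRegressionResults(
            model=m, method="REML", beta=np.zeros(1), cov_beta=np.eye(1),
            tau2_species=t2, gamma2_exp=g2, llf=0.0, converged=True)
        # 0.010 total falling to 0.0082 is an 18.0% reduction
        assert pseudo_r2(mk(0.004, 0.0042), mk(0.006, 0.004)) == pytest.approx(18.0)
        assert pseudo_r2(mk(0.02, 0.0), mk(0.005, 0.005)) == 0.0  # clipped

    def test_mismatched_data_rejected(self):
        rng = np.random.default_rng(13)
        r1 = MetaRegression.from_effects(
            meta_effects(rng, n_species=10, per_species=2), ()).fit("REML")
        r2 = MetaRegression.from_effects(
            meta_effects(rng, n_species=10, per_species=2), ()).fit("REML")
        with pytest.raises(ValueError, match="same data"):
            pseudo_r2(r1, r2)


class TestBlup:
    def test_zero_tau2_gives_zero_blups(self):
        rng = np.random.default_rng(14)
        eff = meta_effects(rng, n_species=10, per_species=2)
        m = MetaRegression.from_effects(eff, ())
        r = MetaRegressionResults(model=m, method="REML", beta=np.zeros(1),
                                  cov_beta=np.eye(1), tau2_species=0.0,
                                  gamma2_exp=0.01, llf=0.0, converged=True)
        assert (r.blup() == 0).all()

    def test_balanced_closed_form(self):
        """Balanced intercept-only design: û_s = shrink · (ȳ_s − ȳ) with
        shrink = τ²/(τ² + (γ² + v)/m)."""
        rng = np.random.default_rng(15)
        S, m_per, v0 = 12, 4, 0.003
        tau2, gamma2 = 0.02, 0.007
        sp = np.repeat([f"s{i}" for i in range(S)], m_per)
        y = rng.normal(0.3, 0.2, S * m_per)
        eff = _simple_effects(y, np.full(S * m_per, v0), sp)
        model = MetaRegression.from_effects(eff, ())
        beta, *_ = model._profile(tau2, gamma2)
        res = MetaRegressionResults(model=model, method="REML", beta=beta,
                                    cov_beta=np.eye(1), tau2_species=tau2,
                                    gamma2_exp=gamma2, llf=0.0, converged=True)
        u = res.blup()
        ybar_s = pd.Series(y).groupby(sp).mean()
        shrink = tau2 / (tau2 + (gamma2 + v0) / m_per)
        expected = shrink * (ybar_s - beta[0])
        np.testing.assert_allclose(u.sort_index(), expected.sort_index(),
                                   atol=1e-6)

    def test_blup_recovery_correlates_with_truth(self):
        rng = np.random.default_rng(16)
        S, m_per = 100, 4
        tau2, gamma2, v0 = 0.02, 0.002, 1e-4
        sp = np.repeat([f"s{i:03d}" for i in range(S)], m_per)
        u_true = rng.normal(0, np.sqrt(tau2), S)
        y = 0.2 + np.repeat(u_true, m_per) + rng.normal(0, np.sqrt(gamma2), S * m_per)
        eff = _simple_effects(y, np.full(S * m_per, v0), sp)
        r = MetaRegression.from_effects(eff, ()).fit("REML")
        u_hat = r.blup()
        order = [f"s{i:03d}" for i in range(S)]
        assert np.corrcoef(u_hat.loc[order], u_true)[0, 1] > 0.8


class TestPredict:
    COEF = {"intercept": 0.0178, "acclim_temp": 0.0010, "trait_ctmin": -0.0158}

    def test_worked_values(self):
        assert predict_from_coefficients(self.COEF, 1.8, "CTmax") == \
            pytest.approx(0.0196, abs=1e-10)
        assert predict_from_coefficients(self.COEF, 40, "CTmax") == \
            pytest.approx(0.0578, abs=1e-10)
        assert predict_from_coefficients(self.COEF, 0, "CTmax") == \
            pytest.approx(0.0178, abs=1e-12)

    def test_fitted_model_prediction_consistent(self):
        rng = np.random.default_rng(17)
        eff = meta_effects(rng, n_species=60, per_species=3,
                           v_log_median=np.log(1e-7))
        r = MetaRegression.from_effects(eff, ("acclim_temp", "trait_type")).fit("REML")
        manual = r.beta[0] + r.beta[1] * 20.0
        assert r.predict(20.0, "CTmax") == pytest.approx(manual, rel=1e-12)

    def test_unknown_trait_level_rejected_and_extrapolation_warns(self):
        rng = np.random.default_rng(18)
        eff = meta_effects(rng, n_species=20, per_species=2)
        r = MetaRegression.from_effects(eff, ("acclim_temp",)).fit("REML")
        with pytest.raises(ValueError, match="trait_type"):
            r.predict(20.0, "TTD")
        with pytest.warns(UserWarning, match="outside"):
            r.predict(80.0, "CTmax")


class TestModelSelect:
    def test_single_candidate_passthrough(self):
        rng = np.random.default_rng(19)
        eff = meta_effects(rng, n_species=20, per_species=3)
        best, table = model_select(eff, candidates=[("acclim_temp",)])
        assert len(table) == 1
        assert best.model.moderators == ("acclim_temp",)
        assert best.method == "REML"

    def test_directional_selection(self):
        """A real temperature effect on the rate is almost always selected;
        a null temperature effect on the capacity usually is not."""
        rng = np.random.default_rng(20)
        temp_in, temp_out = 0, 0
        n_rep = 30
        for _ in range(n_rep):
            rate_eff = meta_effects(rng, n_species=60, per_species=3,
                                    beta=(0.0178, 0.0010, -0.0158),
                                    measure="rate")
            arr_eff = meta_effects(rng, n_species=60, per_species=3,
                                   beta=(0.22, 0.0, 0.05),
                                   tau2=0.08**2, gamma2=0.06**2,
                                   v_log_median=np.log(1e-4),
                                   measure="capacity")
            best_r, _ = model_select(rate_eff)
            best_a, _ = model_select(arr_eff)
            temp_in += "acclim_temp" in best_r.model.moderators
            temp_out += "acclim_temp" not in best_a.model.moderators
        assert temp_in >= int(0.9 * n_rep)
        assert temp_out >= int(0.7 * n_rep)
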