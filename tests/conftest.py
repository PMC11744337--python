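import numpy as np
import pandas as pd
import pytest

from acclim.metareg import MetaRegression
from acclim.simulate import SimConfig, simulate_database
from acclim.timecourse import ExperimentSeries, RescaledSeries


@pytest.fixture
def noiseless_config():
    """Generator settings with every noise source switched off."""
    return SimConfig(
        n_species=5, measurement_sd=0.0, sd_exp_rate=0.0, sd_exp_arr=0.0,
        sd_species_rate=0.0, sd_species_arr=0.0, seed=11,
    )


@pytest.fixture
def small_db():
    db, truth = simulate_database(SimConfig(n_species=8, seed=21))
    return db, truth


def make_series(times, values, trait="CTmax", initial=20.0, acclim=30.0,
                eid="e1", species="sp1"):
    return ExperimentSeries(
        experiment_id=eid, study_id="st1", species=species,
        taxon_class="Amphibia", trait_type=trait,
        initial_temp_C=initial, acclim_temp_C=acclim,
        times=np.asarray(times, float), values=np.asarray(values, float),
    )


def exponential_series(z_inf, lam, times, noise_sd=0.0, rng=None):
    """A rescaled series generated from the saturating-exponential model."""
    t = np.asarray(times, float)
    Z = z_inf * (1.0 - np.exp(-lam * t))
    if noise_sd > 0:
        Z = Z + rng.normal(0.0, noise_sd, t.size)
        Z = np.abs(Z)
        Z[0] = 0.0
    return RescaledSeries(times=t, Z=Z)


def meta_effects(rng, n_species=72, per_species=3,
                 beta=(0.0178, 0.0010, -0.0158),
                 tau2=0.008**2, gamma2=0.015**2, v_log_median=np.log(1e-6),
                 measure="rate", temp_effect=True):
    """Effect sizes drawn directly from the meta-regression's own model."""
    n = n_species * per_species
    sp = np.repeat([f"s{i:03d}" for i in range(n_species)], per_species)
    T = rng.uniform(5, 35, n)
    ctmin = rng.random(n) < 0.3
    X = np.column_stack([np.ones(n), T if temp_effect else np.zeros(n),
                         ctmin.astype(float)])
    v = np.exp(rng.normal(v_log_median, 1.0, n))
    u = np.repeat(rng.normal(0, np.sqrt(tau2), n_species), per_species)
    y = X @ np.asarray(beta) + u + rng.normal(0, np.sqrt(gamma2), n) \
        + rng.normal(0, np.sqrt(v))
    return pd.DataFrame({
        "value": y, "sampling_var": v, "species": sp, "acclim_temp_C": T,
        "trait_type": np.where(ctmin, "CTmin", "CTmax"), "measure": measure,
    })
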