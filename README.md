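# acclim

**Rate and capacity of thermal-tolerance plasticity from acclimation
time-course experiments.**

When an ectotherm is moved to a new temperature, its thermal tolerance
(CTmax or CTmin) drifts toward a new equilibrium. Two numbers describe
that plastic response: the **rate** λ (h⁻¹) at which tolerance approaches
its asymptote and the **capacity** — the asymptotic shift Z∞ (°C),
standardized per degree of acclimation change as the acclimation response
ratio ARR = |Z∞/ΔT| (°C °C⁻¹). `acclim` is a two-stage inference pipeline
for compilations of such experiments, aimed at comparative physiologists
and meta-analysts who want species-level estimates of both quantities and
the relationship between them.

**Stage 1.** Each experiment's tolerance series is rescaled to
Z_t = |z_t − z̄₀| and fitted with the saturating-exponential model

    Z_t = Z∞ (1 − e^(−λt))

by multistart nonlinear least squares (positivity-enforcing
log-parameterization, Gauss–Newton sampling variances, identifiability
guards for flat or ramp-like series).

**Stage 2.** The per-experiment estimates, with their sampling variances
treated as known, enter separate multilevel random-effects
meta-regressions

    y_i = x_iᵀβ + u_{species(i)} + w_i + ε_i,
    u_s ~ N(0, τ²),  w_i ~ N(0, γ²),  ε_i ~ N(0, v_i),

with acclimation temperature and trait type (CTmax/CTmin) as candidate
moderators, AICc model selection under ML, REML reporting, multilevel I²,
pseudo-R² and species-level BLUPs. Species rates (standardized to 20 °C,
CTmax) and capacities (CTmax) are then correlated (Pearson and Spearman)
to ask whether species that acclimate *fast* also acclimate *far*.

The package also ships a synthetic-database generator with known ground
truth (so every stage is testable by parameter recovery) and a
phylogenetic-relatedness diagnostic (Grafen branch lengths, mean
off-diagonal relatedness against the 0.2 reliability threshold).

## Worked example

```python
import acclim

# a synthetic database shaped like the compiled literature:
# 72 species, 3 experiments each, correlated species effects (rho = -0.5)
result = acclim.run_pipeline({"simulate": {"seed": 303}, "n_starts": 6, "seed": 1})

rate = result.effects[result.effects.measure == "rate"].value
arr = result.effects[result.effects.measure == "capacity"].value
c = result.correlation
print(f"experiments retained: {result.exclusion_log['n_retained']}")
print(f"median lambda: {rate.median():.4f} h^-1, median ARR: {arr.median():.3f}")
print(f"rate moderators selected: {result.rate_results.model.moderators}")
print(f"capacity moderators selected: {result.arr_results.model.moderators}")
print(f"pearson r = {c.pearson_r:.3f} (p = {c.pearson_p:.3f}), "
      f"spearman rho = {c.spearman_rho:.3f} (p = {c.spearman_p:.3f}), n = {c.n_species}")
```

prints

```
experiments retained: 216
median lambda: 0.0369 h^-1, median ARR: 0.228
rate moderators selected: ('acclim_temp', 'trait_type')
capacity moderators selected: ('trait_type',)
pearson r = -0.242 (p = 0.042), spearman rho = -0.281 (p = 0.018), n = 71
```

A median rate of ≈ 0.037 h⁻¹ means a typical species completes about half
of its acclimation within a day. Model selection keeps acclimation
temperature and trait type for the rate but only trait type for the
capacity, and the species-level correlation is negative: fast-acclimating
species tend to shift their tolerance by *less* per degree — a
rate–capacity trade-off. (One species here lost its capacity estimate to
a non-converged experiment, hence n = 71.) Because the generating
correlation was −0.5 and the pipeline estimates it through two stages of
noisy inference plus BLUP shrinkage, the recovered −0.24 illustrates the
attenuation one should also expect on real data.

The same analysis runs on any long-format CSV with columns
`experiment_id, study_id, species, taxon_class, trait_type,
initial_temp_C, acclim_temp_C, time_h, tolerance_C` via
`run_pipeline({"database": "path.csv", ...})`, or from the shell:

```
acclim simulate --seed 42 --out db.csv
acclim run-all --config config.yaml --outdir results/
```

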