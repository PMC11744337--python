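# Methods

## The scientific problem

Ectotherms adjust their thermal tolerance (critical thermal maximum, CTmax,
or minimum, CTmin) when held at a new temperature. Two properties of that
plastic response matter for persistence under rapid environmental change:
how *fast* tolerance moves (the plasticity rate) and how *far* it can move
(the plasticity capacity). `acclim` implements a two-stage inference that
estimates both from acclimation time-course experiments and then asks, at
the species level, whether fast acclimators are also large acclimators.

## Stage 1 — exponential acclimation kinetics

Each experiment reports mean tolerance `z_t` (°C) at hours
`t = 0, t_1, …` after an abrupt shift from an initial to a new acclimation
temperature. The series is rescaled to `Z_t = |z_t − z̄_0|`, where `z̄_0`
is the mean of all observations at `t = 0` (several baseline measurements
are averaged; a single `Z = 0` row is retained). The saturating model

    Z_t = Z∞ (1 − e^(−λ t))

is fitted by nonlinear least squares, giving the capacity `Z∞` (°C) and
rate `λ` (h⁻¹). Fitting details:

- **Multistart.** `n_starts` starting points (default 10) with λ drawn
  log-uniformly on [1e-4, 1] h⁻¹ and Z∞ uniformly on [0.25, 4] × max(Z);
  the lowest-RSS converged solution wins, with equal-RSS ties broken
  toward the smaller rate so output is deterministic.
- **Positivity.** The optimizer works on (log Z∞, log λ), which enforces
  Z∞, λ > 0 without active box constraints. Convergence tolerances are
  `ftol = xtol = 1e-12`.
- **Identifiability guards.** Two degenerate ridges exist: λ → 0 with
  Z∞ → ∞ (a linear ramp; the asymptote is unobserved) and λ → ∞ (a step;
  the rate is unobserved). Optima with λ outside [1e-8, 1e3] h⁻¹ or
  Z∞ > 50 × max(Z) are reported as convergence failures, the same outcome
  a standard NLS routine produces on such series. In default simulations
  roughly 1–2% of experiments fail this way, comparable to the convergence
  failures in the compiled literature (10 of 205).
- **Uncertainty.** Gauss–Newton sampling covariance
  `σ̂² (JᵀJ)⁻¹` with `σ̂² = RSS/(n − 2)` and `J` the Jacobian at the
  optimum — the asymptotic variance that downstream meta-analysis treats
  as known.

Capacity is made comparable across experiments as the acclimation response
ratio `ARR = |Z∞ / ΔT|` (°C °C⁻¹), with `ΔT` the difference between new
and initial acclimation temperatures. Two conventions for the ARR sampling
variance are implemented: `paper_literal` (divide `var(Z∞)` by `|ΔT|`, the
convention stated by the source analysis, dimensionally inconsistent but
reproduced as written and used by default) and `delta_method`
(divide by `ΔT²`, the first-order variance of `Z∞/ΔT`). The mode travels
with every output row; neither is silently "corrected". Which convention
the original code used cannot be determined from its description, which is
why both exist.

## Stage 2 — multilevel meta-regression

For each measure (rate λ and capacity ARR) separately:

    y_i = x_iᵀ β + u_{species(i)} + w_i + ε_i,
    u_s ~ N(0, τ²),  w_i ~ N(0, γ²),  ε_i ~ N(0, v_i) known,

with moderators drawn from {acclimation temperature (linear, °C),
trait type (CTmin dummy; CTmax is the reference level)}. The marginal
covariance `V = τ² Z_s Z_sᵀ + γ² I + diag(v)` is optimized over
(τ², γ²) ≥ 0 by L-BFGS-B from three deterministic method-of-moments
starts, with β profiled out by GLS at each step. The REML objective
carries the `+½ log|XᵀX|` constant so it equals the exact log-density of
the error contrasts; tests exploit this for a direct multivariate-normal
audit. No study-level random effect is estimated: in this literature most
studies contribute a single species, which makes study and species
variance inseparable. No phylogenetic species effect is estimated either —
the relatedness diagnostic (below) reports whether separating it from the
nonphylogenetic component would even be reliable.

Model selection fits all four moderator subsets by ML, compares them by
AICc with `p = #β + 2` (variance components counted as parameters, the
convention of standard meta-analytic software; configurable by computing
AICc from `llf` directly), and refits the winner by REML for reporting.
Wald 95% intervals are used throughout, matching the symmetric intervals
reported for this kind of model.

Heterogeneity uses the multilevel I² with the Higgins–Thompson typical
sampling variance `ṽ = (n−1)Σw / ((Σw)² − Σw²)`, `w_i = 1/v_i`:
`I²_level = 100 σ²_level/(τ² + γ² + ṽ)`, summed across levels for the
total. Pseudo-R² is the percent reduction in `τ² + γ²` relative to the
intercept-only model, clipped at 0. Species-level intercepts are BLUPs
`û = τ² Z_sᵀ V⁻¹ (y − Xβ̂)`; with τ̂² = 0 all BLUPs are exactly zero.

## Species estimates and the headline correlation

Each species' rate is the conditional prediction for a CTmax trait at
20 °C (`β̂₀ + 20 β̂_temp + û_s`, temperature term present only when
selected); its capacity is the conditional CTmax prediction from the ARR
model. The association between the two is summarized by Pearson's r (t
test on n − 2 df) and Spearman's ρ (the same approximation on average
ranks) — the t-approximation is standard at n ≈ 70 and is validated in the
tests against a sampled permutation oracle.

When a model's τ̂² lands on the zero boundary the species estimates are
constant and the correlation is deliberately undefined (an error naming
the degenerate stage), not silently zero.

## The synthetic-data generator

The generator emulates the compiled acclimation database: species with
correlated random effects on rate and capacity, studies within species,
experiments within studies, an acclimation-temperature effect on the rate
only, CTmax/CTmin offsets, experiment-level heterogeneity, and
per-timepoint measurement noise. Sign conventions: warming shifts
tolerance up, cooling down, for both traits; only |z_t − z_0| reaches the
fitter, so this cannot affect estimates. Rates and ARRs are generated on
the identity scale and truncated below at 1e-4 h⁻¹ and 1e-3 °C °C⁻¹
respectively; if more than 10% of experiments hit a floor a warning flags
the configuration as unrealistic. A hierarchical seed stream
(species → study → experiment) makes databases bit-identical for a given
seed and insensitive to adding later experiments.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| n_species | 72 | species count of the compiled database |
| studies_per_species / experiments_per_study | 1 / 3 | ≈ 2.7 experiments per species, as observed |
| rate intercept / temp slope / CTmin offset | 0.0178 / 0.0010 / −0.0158 (h⁻¹) | the fitted rate-model coefficients |
| ARR intercept / CTmin offset | 0.22 / +0.05 (°C °C⁻¹) | centres the ARR distribution near the observed 0.24 median, CTmin above CTmax |
| sd_species_rate / sd_exp_rate | 0.008 / 0.015 | splits rate heterogeneity ≈ 20:80 between species and experiment levels, as observed |
| sd_species_arr / sd_exp_arr | 0.08 / 0.06 | splits ARR heterogeneity ≈ 65:35, as observed |
| rho_rate_arr | −0.5 | a negative species-level rate–capacity correlation of moderate strength |
| measurement_sd | 0.02 °C | calibrated so sampling error is a fraction of a percent of total heterogeneity, matching the near-total I² of the fitted models; the time-course values are digitized group means, not individual measurements |
| timepoints | 0, 2, 6, 12, 24, 48, 96, 168 h | spans fast (reptile-like) and slow (fish-like) rates around the observed 0.026 h⁻¹ median |
| temp_range / delta_t_range | 5–35 °C / 2–10 °C | the bulk of acclimation temperatures and shift magnitudes in the literature |
| p_ctmin | 0.3 | CTmax experiments predominate |

What the generator does **not** emulate: digitization error structure of
specific published figures, time-to-death endpoints, unbalanced designs in
which one study spans many species, and phylogenetically correlated
species effects. Passing recovery tests therefore shows the estimators are
correct under the assumed hierarchical-normal world, not that the
published database satisfies those assumptions.

## Relatedness diagnostic

A Newick tree over the species is given Grafen branch lengths — node
height `((#descendant tips − 1)/(n_tips − 1))^ρ`, ρ = 1 by default, tips
at height 0, depth normalized to 1 — and converted to the relatedness
matrix of shared root-to-MRCA path lengths. The mean off-diagonal entry
is compared with 0.2: below that, phylogenetic and nonphylogenetic
species variances cannot be reliably separated, which is the documented
reason the meta-regression estimates only the nonphylogenetic component.
Polytomies are handled natively by the height rule (no random
resolution). Trees are consumed from files only; no remote tree service
is contacted.

## Numerical choices and edge cases

- Variance components are optimized on the identity scale with
  non-negativity bounds; log-scale optimization was rejected because the
  τ² = 0 boundary is a legitimate estimate.
- The closed-form equal-variance case identifies only τ² + γ² (one effect
  per species); tests compare the sum.
- Zero sampling variances are tolerated: the typical sampling variance is
  computed over positive-variance effects with a warning.
- Rank-deficient fixed-effect designs are rejected with the collinear
  columns named.
- AICc requires an ML fit and `n > p + 1`; both are enforced.
- The eligibility filter applies rules in order (TTD endpoint, < 3
  post-baseline timepoints, missing temperatures) and counts each
  experiment once, so exclusions plus retained always equal the input
  count.

## Problem sizes used in tests and the acceptance script

Recovery and oracle checks run at the database scale of the compiled
literature (72 species, ≈ 216 experiments) with 50–200 replicates for
distributional claims and 100 series for the grid-search oracle; these
sizes give stable pass/fail behaviour for the stated thresholds on a
single CPU. All randomness flows from explicit seeds.

## Known limitations

- The Gauss–Newton variance understates uncertainty for series fit near
  an identifiability ridge; the guards exclude the worst cases but the
  retained tail is still heavier than Gaussian.
- The `paper_literal` ARR variance is not on the ARR scale; it is the
  default only to reproduce the source convention, and any serious
  reanalysis should compare both modes.
- Wald intervals on variance-component models can undercover slightly;
  observed fixed-effect coverage in the recovery simulations sits near
  97%.
- With two or fewer effects per species, τ̂² = 0 boundary estimates occur
  in a few percent of simulated databases; the pipeline surfaces these as
  errors rather than producing a spurious zero correlation.
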