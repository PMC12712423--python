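# traitshift

Bayesian analysis of ontogenetic shifts in plant functional traits — how
leaf and wood-anatomy traits change as woody plants grow from seedlings into
adults, and whether the trait trade-off axes seen in adults already exist in
seedlings.

The package is aimed at plant trait ecologists working with
population-level trait tables (one row per species × site × life stage). It
was built around a tropical dry-forest setting: four sites along a rainfall
gradient, eight traits — leaf area (LA, cm²), leaf dry matter content
(LDMC, g g⁻¹), specific leaf area (SLA, cm² g⁻¹), wood specific gravity
(WSG), fiber wall thickness (TFW, μm), hydraulically weighted vessel
diameter (d_h, μm), vessel density (VD, mm⁻²) and pit aperture diameter
(DA_pit, μm) — with LA, SLA, d_h, VD and DA_pit analyzed on log scales and
all traits standardized.

## What it computes

**Ontogenetic shift models.** For each trait, the paired difference between
the standardized adult and seedling value of the same population,
Δᵢ ~ Normal(μᵢ, σ²), is fitted three ways:

* overall: μᵢ = μ;
* by site: μᵢ = α_k (cell-means coding, one intercept per site), with
  posterior pairwise site contrasts α_j − α_k and a compact letter display
  (sites share a letter iff their shifts do not differ significantly);
* full: μᵢ = α_k·siteᵢ,k + β₁·deciduousᵢ + β₂·lianaᵢ, where β₁ is the
  effect of being deciduous and β₂ the effect of being a liana (evergreen,
  free-standing is the reference class).

An effect is "significant" when its 95% equal-tailed credible interval
excludes zero.

**Bayesian PCA with varimax rotation.** The posterior of the trait
covariance matrix (conjugate inverse-Wishart sampling) is pushed through
eigendecomposition, loading scaling (eigenvector × √eigenvalue), varimax
rotation and sign/permutation alignment, yielding posterior medians and
50%/95% credible intervals for every loading and for the variance explained
by each rotated component. Run separately for adults, seedlings, and both
stages combined (DA_pit is excluded from the combined ordination because
seedling and adult measurements of it are not methodologically comparable).

**Posterior correlations and stage contrasts.** Trait pairs within a stage
are modeled as bivariate normal; ρ is derived from each covariance draw.
Where a pair's correlation is similar between stages, per-stage simple
regressions are fitted and the posteriors of intercepts and slopes are
differenced (β_seedling − β_adult, α_seedling − α_adult).

**Inference engine.** All models share conjugate Gibbs samplers (three
chains × 4000 iterations, 1000 burn-in, vague priors) and classic
Gelman-Rubin R̂ diagnostics with the conventional 1.1 threshold.

**Synthetic data.** A generator emulates a realistic sampling design: a two-factor
latent trait structure (hydraulic safety–efficiency axis: d_h, VD, DA_pit,
TFW; tissue-investment axis: SLA, LDMC, WSG), per-trait stage shifts with
site/phenology/growth-form effects, partial stage pairing, per-cell
missingness — with the ground truth stored so every stage of the pipeline
is verifiable without external data.

## Worked example

```python
from traitshift import (MCMCConfig, SyntheticConfig, TRAIT_NAMES,
                        complete_cases, fit_bayes_pca, fit_overall_shift,
                        generate_dataset, pair_stages, transform_and_standardize)

table, truth = generate_dataset(SyntheticConfig(seed=1))
std = transform_and_standardize(table)            # pooled log + z-score
shift = fit_overall_shift(pair_stages(std, "SLA"), MCMCConfig(seed=1))
s = shift.overall
print(f"SLA shift (adult - seedling): {s.mean:.2f} "
      f"[{s.ci_low:.2f}, {s.ci_high:.2f}], R-hat {s.rhat:.3f}, "
      f"n = {shift.n_populations}, significant = {s.significant}")

adults = transform_and_standardize(table, scope="adults_only")
cc = complete_cases(adults, list(TRAIT_NAMES), stage_filter="adults_only")
pca = fit_bayes_pca(cc, k=2, config=MCMCConfig(seed=2))
for j in range(2):
    print(f"component {j+1}: {100*pca.varexp_median[j]:.1f}% of variance "
          f"[{100*pca.varexp_ci_low[j]:.1f}%, {100*pca.varexp_ci_high[j]:.1f}%]")
```

prints

```
SLA shift (adult - seedling): -0.76 [-0.97, -0.56], R-hat 1.000, n = 38, significant = True
component 1: 24.6% of variance [21.8%, 27.7%]
component 2: 22.6% of variance [19.9%, 25.5%]
```

i.e. on this synthetic dataset SLA drops by about three quarters of a
pooled standard deviation from seedling to adult (clearly significant: the
interval is far from zero), and the first two rotated components of the
adult ordination each carry roughly a quarter of the total trait variance.

A command-line interface mirrors the library:

```bash
traitshift synth --seed 1 --out run/          # synthetic table + ground truth
traitshift run   --seed 1 --out run/          # full pipeline
traitshift run --config my_run.yaml --seed 7  # custom YAML configuration
```

Every run writes per-stage TSV/JSON results, a convergence report flagging
any R̂ ≥ 1.1, the resolved configuration and a log; re-running with the
same config and seed reproduces all numeric outputs byte for byte.

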