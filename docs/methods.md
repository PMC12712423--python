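# Methods

This note records the statistical models implemented in `traitshift`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model and standardization

The analysis unit is a population (species × site), observed at the
seedling and/or adult stage, with up to eight trait values. LA, SLA, d_h,
VD and DA_pit are treated as log-normal and natural-log-transformed before
analysis; LDMC, WSG and TFW are analyzed on their natural scale. The base
of the log is cosmetic (it cancels after z-scoring and in correlations) and
is fixed to e for reproducibility.

Each trait is z-scored (sample SD, ddof = 1) over the non-missing cells of
the chosen scope. The default scope for the shift analyses is *pooled over
both stages and all sites*, so a shift of 1.0 means one pooled-SD unit and
seedling and adult values live on one common scale. Stage-specific scopes
(`adults_only`, `seedlings_only`) are used for the per-stage ordinations
and are available as configuration for the shift models as well, without
endorsing either convention as canonical. An explicit `center`/`scale`
override supports standardizing against a fixed external reference — the
synthetic-data workflow uses it to express fitted parameters on the exact
scale on which the ground truth was generated.

Missingness is handled per cell, not per row: each analysis selects its own
complete set, so per-trait sample sizes differ, as they do in real trait
tables. No imputation is performed.

## Shift models

Paired standardized differences Δᵢ = adultᵢ − seedlingᵢ are modeled as
Δᵢ ~ Normal(μᵢ, σ²) with a single shared σ per trait-model (a per-site σ is
available as an option on the site model). The three nested mean
structures are: overall (μᵢ = μ), site (μᵢ = α_k, cell-means coding with no
global intercept so that pairwise contrasts are direct posterior
differences), and site + phenology + growth form
(μᵢ = α_k + β₁·deciduousᵢ + β₂·lianaᵢ; evergreen free-standing is the
reference class absorbed into the site intercepts). An indicator column
that is constant within a trait's paired subset (e.g. no lianas survived
pairing) makes its coefficient unidentifiable; it is dropped with a logged
warning rather than erroring so the same model runs across per-trait
subsets. Populations recorded with unknown phenology or growth form fall
into the reference class.

The compact letter display assigns letters to the maximal cliques of the
"not significantly different" graph over sites, ordered by lowest-numbered
member. With an edge for every non-significant pair, any such pair lies in
some maximal clique and any significant pair in none, so two sites share a
letter iff they do not differ — exactly, verified by exhaustive enumeration
at the four-site scale.

## Samplers and priors

All posteriors come from conjugate Gibbs samplers, run as three chains of
4000 iterations with the first 1000 discarded (defaults; configurable).
Priors are deliberately vague:

* locations and regression coefficients: Normal(0, 100²);
* residual SD: Uniform(0, 100) on σ, implemented as a truncated
  inverse-gamma conditional (rejection sampling; inverse-CDF fallback), with
  a conjugate InvGamma(0.001, 0.001) alternative selectable in the config;
* covariance matrices: Inverse-Wishart(I, d + 1), alternated with the mean
  vector under a flat prior: μ | Σ ~ Normal(ȳ, Σ/n) and
  Σ | μ ~ InvWishart(I + S_μ, d + 1 + n).

Chains start overdispersed around the closed-form estimate (chain c at
estimate + (c − 1 − (C−1)/2) · 2 SE; covariance chains scale the sample
covariance up/down), which makes the Gelman-Rubin diagnostic meaningful.
The classic two-part R̂ = √((n−1)/n + B/(nW)) is used rather than split-R̂
(a chain with zero within-chain variance reports +∞); split-R̂ would be a
straightforward extension but is not what this class of ecological
analyses conventionally reports. Credible intervals are equal-tailed —
the bracketed [low, high] style — with HPD intervals available as an
option. No thinning is applied.

Two deterministic conventions are worth noting. The normal-mean and linear
samplers run on sign-canonicalized data (s·y with s the sign of Σy) and map
location draws back by s; because the coefficient prior is symmetric about
zero this is distributionally exact, and it makes negating the data negate
every location draw bit-for-bit. Similarly, the correlation model orders
its two variables by trait name internally, making ρ exactly symmetric in
its arguments.

## Bayesian PCA with varimax rotation

Per posterior draw of Σ: convert to a correlation matrix, eigendecompose,
form loadings L = V_k diag(√λ_k) (so squared loadings sum to eigenvalues
and variance explained is λ_j/p before rotation and Σᵢ L̃²ᵢⱼ/p after),
varimax-rotate, and align. Varimax uses the SVD-based iteration on the raw
criterion Σⱼ[mean(L⁴·ⱼ) − mean(L²·ⱼ)²] without Kaiser row normalization by
default (Kaiser is a flag); rotation is orthogonal, so communalities and
the k-subset variance total are preserved to numerical precision.

Because rotation leaves column order and sign arbitrary draw to draw, each
rotated draw is aligned to a deterministic reference — classical PCA +
varimax of the sample correlation matrix, columns ordered by variance
explained and oriented so each column's largest-magnitude element is
positive — by exhaustively choosing the column permutation and signs that
maximize the total |correlation| with the reference (k! · 2^k options,
exact for the k ≤ 6 supported). Elementwise medians and equal-tailed
50%/95% quantiles over aligned draws give the reported loadings; scores are
least-squares projections onto the median loadings. A (near-)repeated
eigenvalue in the reference decomposition makes the rotation indeterminate
and is a hard error. Combined-stage ordinations must exclude DA_pit (its
seedling and adult measurements are not comparable); this is enforced.

## Correlations and stage regression contrasts

ρ is derived per covariance draw as Σ₁₂/√(Σ₁₁Σ₂₂). The stage regression
comparison fits y ~ x independently per stage (pooled standardization, so
intercepts are comparable) and forms difference posteriors by pairing the
two independent fits' draws in iteration order — any fixed pairing of
independent draws is a draw from the difference distribution. The
dependent variable of a pair is the trait with the larger absolute overall
shift (ties break lexicographically, logged). The comparison runs when
|ρ_adult − ρ_seedling| ≤ 0.2 by default — "similar correlations" has no
standard numeric definition, so the threshold is a package choice,
overridable and bypassable with a force flag.

## Synthetic data generator

For population i with latent factors fᵢ ~ N(0, diag(factor_sd²)):

    seedling_i = L_s f_i + ε_i,            ε_i ~ N(0, diag(resid_sd²))
    adult_i    = L f_i + ε_i + δ_i,        δ_i,t ~ N(α_t[site] + β₁,t·dec_i + β₂,t·liana_i, sd_t²)

L couples d_h (+0.90), VD (−0.87), DA_pit (+0.60), TFW (−0.50) and part of
WSG (−0.35) to the hydraulic axis and SLA (+0.85), LDMC (−0.83), WSG
(−0.60) and LA (+0.30) to the tissue axis; residual SDs bring each trait's
variance to ~1 on the generation scale. L_s zeroes the hydraulic-axis
loadings of the traits listed in `decouple_seedling_traits` (default
DA_pit and TFW), rescaling any remaining row entries to preserve the row
norm. Adults use the full L with the same factors and residuals, so for
non-decoupled traits adult = seedling + δ exactly and paired differences
follow the shift model's normal law, while decoupled traits regain their
hydraulic coupling only in adults — reproducing the stage-dependent
integration of wood traits. `implied_correlation` returns the exact
generator correlation L diag(factor_sd²) Lᵀ + diag(residual variance) per
stage, with the shift noise counted as adult residual variance; it is
conditional on the covariates (site/phenology/growth-form mean structure is
not part of it).

Default shift parameters are per-trait, mirroring the magnitudes reported
for this system (e.g. SLA ≈ −1.0 pooled-SD units overall with a stronger
decline for deciduous species, d_h ≈ +1.0, DA_pit ≈ −2.0, VD ≈ 0); site
intercepts spread around each trait's mean shift by up to ±0.6. Covariate
mix: 40% deciduous, 15% lianas. The sampling design defaults reproduce a realistic campaign
composition: 61 populations per site, 16% observed at both stages,
unpaired populations keeping their adult record with probability 0.9, and
3% per-cell missingness — giving ≈ 224 adult, ≈ 60 seedling and ≈ 40
paired populations. Natural-unit mappings are fixed per trait (e.g. SLA
log-mean 5.0 → ~150 cm² g⁻¹, WSG mean 0.60); values of bounded traits
(LDMC ∈ (0,1], WSG ∈ (0,2), TFW > 0) are redrawn per cell up to a retry
cap. A `uniform_shift` constructor sets one (α_k, β₁, β₂, σ) set for all
traits, which the recovery tests use.

What the generator does *not* emulate: phylogenetic signal, spatial
structure within plots, height–vessel allometry, species shared across
sites (populations are independent by construction), and trait-shift noise
correlated across traits. The last point matters for interpretation:
because δ is independent across traits, adult-stage correlations are
diluted relative to seedlings by the shift variance, so passing tests show
correct recovery of the generator's structure, not that real adult
correlations would be this weak.

## Problem sizes and numerical choices

The test suite runs every model at field-realistic sizes stated in its
docstrings (e.g. 200 calibration replicates at n = 40 pairs; 100 ordination
replicates at n = 200; a full pipeline at the ≈ 290-record study scale).
Within replicated calibration loops the chains are shortened (2 chains,
500–750 iterations, burn-in scaled accordingly) — coverage of a 95%
interval is insensitive to the number of posterior draws once the quantiles
are stable — while single-dataset recovery and oracle checks use the full
three-chain, 4000-iteration protocol. Tolerances follow the operation
contracts: sampler-vs-oracle agreement within Monte-Carlo error or the
stated absolute bounds (±0.02 for coefficients against OLS at 9000 draws,
±0.07 for ρ against the sample Pearson r — the identity Wishart prior
shrinks ρ toward zero by O(d/n), which is prior influence, not error),
exact-to-1e-10/1e-12 checks for algebraic invariants.

Degenerate inputs are handled explicitly: constant responses floor the
Gibbs sum of squares at a tiny positive value; a constant trait column is a
hard error at standardization; rank-deficient designs name their collinear
columns; zero-variance loading columns count as zero correlation during
alignment.

## Known limitations

* The covariance sampler requires complete cases and n > d; there is no
  missing-data ordination.
* Exhaustive loading alignment restricts the ordination to k ≤ 6
  components (k = 2 is the scientific default here).
* The letter display is exact but brute-force; it is intended for a
  handful of sites, not dozens.
* Stage seeds derive from the master seed by a fixed counter scheme
  (`SeedSequence((master, counter))`); adding pipeline stages never
  perturbs earlier stages' streams, but changing a stage's internal number
  of fits re-seeds the fits after it within that stage.
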