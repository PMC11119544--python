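# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not establish.

## Trait model and Pagel's λ

A continuous trait measured at the tips of a rooted tree with branch
lengths is modelled as multivariate normal, `y ~ N(μ·1, σ²·C(λ))`. `C` is
the Brownian-motion expected covariance — entry (i, j) is the shared
root-to-tip path length of tips i and j, i.e. the depth of their most
recent common ancestor — and `C(λ)` multiplies the off-diagonal by
λ ∈ [0, 1]. λ = 1 leaves the Brownian structure intact; λ = 0 removes all
phylogenetic covariance. A branch length on the root, when present, is
treated as a stem shared by every tip; this convention makes subtree
extraction commute exactly with row/column selection of `C`. Trees need
not be ultrametric (the Brownian algebra does not require it); zero-length
branches are accepted with a warning because grafted megatrees contain
them, and negative lengths are rejected.

### Estimation

For fixed λ, `μ̂(λ)` and `σ̂²(λ)` have closed-form generalized least
squares solutions, so λ is found on the profile likelihood. The profile
can be flat or multimodal, so the maximizer uses a 21-point grid pre-scan
followed by bounded scalar refinement (tolerance 1e-6) between the
neighbours of the best grid point; the endpoints λ = 0, 1 are always kept
as candidates. All linear algebra goes through Cholesky factorization;
a singular covariance (e.g. duplicate tips at zero distance with λ = 1)
raises a named error rather than producing noise.

Degenerate inputs: a star tree makes the likelihood constant in λ — the
fit reports λ̂ = 0 with an explicit non-identifiability flag; a constant
trait is reported as degenerate with a permutation p of 1 by convention.

### Significance

Two tests are reported. The likelihood-ratio statistic 2(ℓ(λ̂) − ℓ(0)) is
referred to the 50:50 mixture of χ²₀ and χ²₁ (the halved p appropriate
for a parameter on its boundary). The randomization test permutes trait
values across tips and re-estimates λ; the permuted statistic is the λ
estimate itself (the likelihood-ratio variant is available via
`statistic="loglik"`). Inside the permutation test both the observed and
permuted estimates are maximized over the same fixed 101-point λ grid,
with one Cholesky per grid point reused across all permutations — this
keeps observed and null draws exchangeable (the p-value is valid by
construction, with (1 + count)/(n_perm + 1)) and makes 1000
randomizations cheap. The reported point estimate still comes from the
refined optimizer; only the test statistic is grid-valued.

### Ancestral states

Internal-node states under Brownian motion are the GLS/BLUP estimates
`μ̂ + Cov(node, tips) C⁻¹ (y − μ̂1)` with `μ̂` the GLS root state; at a
tip this returns the observation exactly. States along a branch are
interpolated linearly between the endpoint estimates.

## Phylogenetic linear mixed model

Site–species rows follow `y = Xβ + Za + Zs + e` with
`a ~ N(0, σ²p Λ)`, `s ~ N(0, σ²s I)`, `e ~ N(0, σ²e I)`; `Z` maps rows to
species and Λ is the Brownian covariance of the pruned tree rescaled to
unit diagonal. The rescaling puts σ²p on the trait-variance scale, which
is what lets R²p be read as a variance fraction. Covariates enter raw by
default (coefficients per natural unit); z-scoring is available.

**ML/REML.** β is profiled by GLS; the three variances are optimized on
the log scale (L-BFGS-B, three starts — equal split, phylogeny-heavy,
residual-heavy — objective tolerance 1e-8, bounds 1e-8·var(y) to
1e3·var(y), with a component pinned at the lower bound reported as zero).
The marginal likelihood is evaluated through the Woodbury identity on the
species-level matrix: with `A = σ²p Λ + σ²s I = LLᵀ`,
`det V = det(I + Lᵀ Z'Z L / σ²e)·σ²e^n` and `V⁻¹` needs only the q×q
factor, so a 900-row, 300-species fit costs milliseconds per evaluation
and agrees with the dense multivariate-normal density to machine
precision.

**Identifiability.** If every species has exactly one row, σ²s and σ²e
enter only through their sum; the fit refuses with an instruction to
aggregate. If Λ is the identity (a star phylogeny), σ²p and σ²s are
jointly unidentifiable; the fit proceeds but records an explicit warning.

**Bayesian backend.** A Gibbs sampler with flat priors on β and
inverse-gamma(0.001, 0.001) priors on each variance. The location block
(β, a, s) is sampled jointly from its Gaussian full conditional:
conditioning β on the species effects would mix catastrophically because
the intercept is nearly collinear with the mean of `a` (joint-block
sampling raised the intercept's effective sample size from ~1 to several
hundred in our checks). Defaults 6000 iterations, 1000 burn-in, thin 5.
Summaries follow the conventions of Bayesian animal models: posterior
mean, central 95% interval, autocorrelation-based effective sample size,
and pMCMC = 2·min(P(β>0), P(β<0)); an effective sample size below 50 for
any parameter is recorded as a warning. The chain is returned for audit.

### Variance partition

With σ²f the variance (ddof 1) of the fitted fixed-effect predictor
across rows and total = σ²f + σ²p + σ²s + σ²e:

- R²p = σ²p / total, R²s = σ²s / total,
- R²c = (σ²f + σ²p + σ²s) / total (conditional R²),
- R²m = σ²f / total (marginal R², the default).

The marginal convention for R²m was chosen because it is the standard
mixed-model decomposition and is the only reading under which the three
reported statistics of such models satisfy R²c − R²p − R²s = R²m; an
alternative "residual" convention, σ²f/(σ²f + σ²e) — the share of the
non-(phylogeny+species) variance captured by the fixed effects — is
available behind a flag.

### Subset selection

All 2^k subsets of ≤ 12 candidates are ranked by an OLS information
criterion; the screen is deliberately a fast OLS surrogate rather than a
re-fit of the mixed model per subset. AIC is the default, matching common
practice for dredge-style tables, but AIC retains a pure-noise candidate
with asymptotic probability P(χ²₁ > 2) ≈ 0.157, so the probability of
recovering an exact support of one true predictor among four candidates
plateaus near 0.84³ ≈ 0.60 regardless of sample size. Consistent
exact-support recovery therefore uses `criterion="bic"`, and that is the
setting exercised by the support-recovery benchmark. Ties within 1e-9 go
to the smaller subset, then lexicographic order.

### Importance and partial effects

Permutation importance wraps any caller-supplied fitted regressor
(`predict(table) -> array`): the score is the mean relative MSE increase
(×100, the %IncMSE convention) over seeded column shuffles; the identity
permutation scores exactly zero, and ranks are 1..k by descending score.
The command-line pipeline supplies an OLS linear model as its default
regressor. Partial effects return partial-residual pairs and the fitted
coefficient with its interval; the sign is the reported effect direction.

## Dataset operations

Filtering applies rules in a fixed order, logging the first failure per
record: valid in-range coordinates → species-level name (≥ 2 tokens,
alphabetic epithet, underscores accepted as separators, placeholder
epithets like "sp."/"cf." rejected) → positive density → optional
tree-species allowlist. Site identity is the coordinate pair rounded to
five decimals (≈ 1 m), which guards against float noise without merging
distinct sites; densities are averaged per (site, species) cell and
covariates must agree within a cell. Species climate zones use the
species' mean MAT over its sites with both boundaries closed on the
temperate side (20 °C and 5 °C are temperate).

Whittaker biome polygons are shipped as replaceable YAML data — a
straight-edge digitization of the classic MAT × MAP diagram drawn for
this package (the diagram's published versions differ slightly; ours is
documented in the data file and swappable). Points on a shared edge go to
the polygon listed first; out-of-polygon points are assigned to the
nearest polygon with both axes normalized to unit range (otherwise
millimetres of rain dominate degrees of temperature) and flagged.

Group comparison is a one-way ANOVA with least-significant-difference
pairwise t tests on the pooled mean square error, Bonferroni-adjusted by
the number of pairs, summarized by an insert-and-absorb compact letter
display (highest mean lettered first).

## Synthetic data generator

The generator reproduces the model's exact structure: a pure-birth
(Yule) ultrametric tree; species effects `a` drawn from
σ²p·Λ(λ) (unit-diagonal correlation) and `s` iid; per-site covariates
independent uniform over documented real-world ranges
(MAT −15…30 °C, MAP 0…4500 mm, clay 5–60 %, NDVI 0.05–0.95, …); rows
`y = intercept + βx + a + s + e` at unique jittered coordinates. Defaults
emulate the study conditions of a global wood-density synthesis: mean
density ≈ 0.57 g/cm³, pooled SD ≈ 0.20, variance split ≈ 84% phylogeny /
8% species / ~1% environment / ~7% residual, with zero-effect decoy
covariates (soc, slope, aspect). Multi-clade configurations join
independently simulated, height-normalized clade subtrees at a shared
root (cross-clade phylogenetic covariance zero), each clade with its own
true λ.

Because a Gaussian additive model can produce non-positive densities in
the far tail (~0.2% of rows at the defaults), the generator redraws the
row residual for such rows (`ensure_positive=True`); distribution-law
tests disable this. Tip labels are binomial-style names so generated
tables pass the record filter unchanged.

What the generator does **not** emulate: spatial autocorrelation of
climate, covariate collinearity (unless supplied), sampling imbalance
across species, measurement protocol differences, and taxonomic noise.
Passing benchmarks therefore demonstrate correctness of the estimators
under the model's own assumptions, not robustness to violations of them.

## Benchmark problem sizes

Chosen so the whole suite and the acceptance script each run in a few
minutes on one CPU: λ recovery uses 100 simulations per true value
(60 in the script) on 200-tip trees; randomization calibration 500
replicates × 199 permutations (300 in the script) on 100-tip trees;
partition recovery 20 replicates (12 in the script) at 300 species × 3
sites; selection 100 replicates at n = 2000; the Gibbs sampler's recovery
checks run at ~100 species with shortened chains. Headline numbers from
the original global dataset (λ = 0.77; R²p = 0.843) require that 27k-record
compilation plus a megatree and are not reproducible from synthetic data;
the package reproduces the *procedure* and its statistical behaviour.

## Known limitations

- The λ optimizer is exact only up to the grid-plus-refinement scheme;
  a profile with two near-equal local maxima finer than the 21-point grid
  could in principle be missed.
- The OLS selection screen ignores the random-effect structure; a
  covariate whose effect is visible only after conditioning on phylogeny
  may be missed.
- The Gibbs sampler's inverse-gamma priors are weakly informative, not
  flat; with very few species per variance component the prior is not
  negligible.
- Biome assignment is only as good as the packaged polygon digitization;
  users comparing against other digitizations should supply their own
  vertex file.
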