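# phylodens

Evolutionary history versus current environment for a continuous
functional trait — wood density — across a phylogeny.

Wood density (oven-dry mass per unit volume, g/cm³) is a central
functional trait of trees: it tracks growth rate, mortality, hydraulic
safety, and carbon content. `phylodens` quantifies how much of its
variation across species is carried by **evolutionary history** (shared
ancestry on a phylogeny, plus species identity independent of that
ancestry) and how much by the **current environment** (climate, soil,
productivity), the comparative-analysis design used in global trait
syntheses.

## What it computes

**Phylogenetic signal (Pagel's λ).** The trait across tips is modelled as
multivariate normal with covariance σ²·C(λ), where C is the
Brownian-motion shared-path-length matrix of the tree and C(λ) multiplies
its off-diagonal by λ ∈ [0, 1] (λ = 1: Brownian expectation; λ = 0:
phylogenetic independence). λ is estimated by profile maximum likelihood
and tested two ways: a boundary-corrected likelihood-ratio test against
λ = 0 and a randomization test permuting trait values across tips.

**Phylogenetic linear mixed model.** At site–species level,

```
y = Xβ + Za + Zs + e,
a ~ N(0, σ²p Λ),  s ~ N(0, σ²s I),  e ~ N(0, σ²e I)
```

with Λ the unit-diagonal Brownian correlation of the pruned tree, `a` the
phylogenetic species effect, `s` the independent species effect (recent
convergent/divergent evolution), and `e` the site residual. Fitting is by
ML/REML (Woodbury-factorized marginal likelihood) or a conjugate Gibbs
sampler with MCMCglmm-style summaries (Post.mean, 95% CI, Eff.samp,
pMCMC). Variance is partitioned as R²p = σ²p/total, R²s = σ²s/total,
R²c = (σ²f+σ²p+σ²s)/total, R²m = σ²f/total, with σ²f the variance of the
fixed-effect predictor.

**Around the core:** record filtering and site–species aggregation;
climate-zone classification (species mean MAT: > 20 °C tropical, 20–5 °C
temperate, < 5 °C boreal); Whittaker biome assignment in (MAT, MAP) space
from packaged, replaceable polygons; one-way ANOVA with LSD post-hoc,
Bonferroni adjustment, and compact letters; exhaustive AIC/BIC subset
selection; environment-only multiple-regression R²; %IncMSE-style
permutation importance around any fitted regressor; Brownian-motion
ancestral state reconstruction with branch interpolation; and a synthetic
data generator reproducing the exact statistical structure above.

## Worked example

```python
import pandas as pd
from phylodens import synthetic, dataset, phylo_signal, pmm

# a synthetic global dataset: 300 species, 3 sites each, ~84% of trait
# variance carried by phylogeny (the generator's documented defaults)
sim = synthetic.simulate_table(synthetic.SimConfig(n_species=300, seed=1))

kept, log = dataset.filter_records(sim.table)      # 900 rows kept, 0 rejected
agg = dataset.aggregate_site_species(kept)
trait = dataset.species_mean(agg)

fit = phylo_signal.fit_lambda(trait, sim.tree)
perm = phylo_signal.permutation_test(trait, sim.tree, n_perm=499, seed=2)
print(f"lambda = {fit.lambda_hat:.2f}, LRT p = {fit.lrt_p:.2g}, "
      f"perm p = {perm.perm_p:.3f}")
# lambda = 0.90, LRT p = 3e-41, perm p = 0.002

design = pmm.build_design(agg, sim.tree, ["mat", "map", "clay", "ndvi"])
res = pmm.fit_pmm_ml(design)
print({k: round(v, 3) for k, v in res.partition.items()})
# {'R2m': 0.005, 'R2c': 0.94, 'R2p': 0.859, 'R2s': 0.076}
```

`lambda = 0.90` says species resemble their relatives almost as strongly
as pure Brownian evolution predicts (the species-level effect dilutes it
slightly below the generating λ = 1); both tests call the signal
significant. The partition attributes ~86% of site–species variance to
phylogeny and ~8% to species identity, while the four environmental
covariates explain under 1% — evolutionary history dominates, matching
the structure the generator was configured to produce.

The same analysis runs from the shell on any Newick + CSV pair:

```sh
phylodens simulate --seed 1 --out demo
phylodens report --seed 1 --out demo \
    --tree demo/simulated_tree.nwk --table demo/simulated_table.csv
```

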