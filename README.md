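# streamcom

**Land use, stream environments, and microbial community assembly.**

`streamcom` is an analysis pipeline for stream metacommunity data: it asks
how regional land use (agricultural vs. forested catchments) shapes local
stream environments — water conductivity, pH, temperature, total
phosphorus, and the N:P ratio — and, through them, the assembly of
bacterial and eukaryotic communities observed as presence-absence
(OTU-by-site) matrices.

The pipeline has four statistical components:

1. **A hierarchical joint species distribution model (JSDM).** Occurrence
   of taxon *j* at site *i* follows a Bernoulli-probit model

   y<sub>ij</sub> = 1{z<sub>ij</sub> > 0},
   z<sub>ij</sub> = x<sub>i</sub>β<sub>j</sub> + Σ<sub>h</sub> η<sub>ih</sub>λ<sub>hj</sub> + ε<sub>ij</sub>,
   ε<sub>ij</sub> ~ N(0, 1),

   where x<sub>i</sub> holds the intercept, a land-use indicator, and the
   five (log-transformed, standardized) environmental covariates. Niche
   coefficients are structured by traits and phylogeny through a
   matrix-normal prior B ~ MN(ΓTᵀ, V, ρC + (1 − ρ)I): T is the trait
   design (trophic mode, and domain for the cross-domain model), C the
   phylogenetic correlation from a Newick tree, and ρ ∈ [0, 1] the
   phylogenetic weight. The residual site-level random effect is a set of
   latent factors with spatial Gaussian-process priors exp(−d/α). The
   model is fitted with a bespoke Gibbs sampler (all conditionals closed
   form; ρ and the spatial ranges α on discrete grids).
2. **A Gaussian environment model** with land use as the fixed effect and
   the same spatial latent-factor random effect, giving per-variable R²
   split into land-use and spatial shares.
3. **Variance partitioning and a causal-flow summary**: each taxon's
   explained variance is split among covariate groups and the spatial
   random effect; combined with the environment model this yields the
   land-use → environment → community flow diagram (plus Tjur R², AUC,
   and Gelman-Rubin psrf diagnostics, and 90%-posterior-probability
   response summaries by trophy × domain).
4. **Region-of-common-profile (RCP) clustering**: square-root binary
   Jaccard dissimilarity, cascading K-means over K = 1..10 with many
   random restarts, Calinski-Harabasz selection of K, and RCP × land-use
   association.

A synthetic-data generator produces study-shaped datasets (default 120
sites split 60/60 between land-use classes, 217 taxa of which 58
bacteria, pure-birth phylogenies per domain) with known ground truth, so
every stage can be validated by parameter recovery.

## Worked example

```python
import streamcom as sc
from streamcom.config import RunConfig, MCMCSchedule
from streamcom.io import filter_taxa

# a study-shaped synthetic dataset with known ground truth
data = sc.simulate_dataset(n_sites=120, n_taxa=217, seed=1)
cm = filter_taxa(data["community"], min_prevalence=10, max_prevalence=119)

# fit the cross-domain community model (no phylogeny, traits incl. domain)
cfg = RunConfig(mcmc=MCMCSchedule(n_chains=2, n_iterations=4000,
                                  burn_in=2000, thin=10))
spec = sc.build_model_spec(data["sites"], cm, data["traits"].loc[cm.taxa],
                           C=None, config=cfg)
post = sc.gibbs_sample(spec, cm, cfg, seed=1)
vp = sc.variance_partition(spec, post)

# fit the environment model and combine into the causal-flow summary
env_post = sc.fit_env_model(data["sites"], RunConfig(
    mcmc=MCMCSchedule(n_chains=2, n_iterations=2000, burn_in=500, thin=5)),
    seed=1)
cf = sc.causal_flow(sc.env_variance_partition(env_post), vp)
print(round(cf.env_mean_r2_pct, 1))
print({k: round(v, 1) for k, v in cf.community_shares.items()})
```

This prints:

```
70.3
{'environment': 72.7, 'land_use': 11.2, 'spatial': 16.2}
```

meaning that land use and spatial location together explain about 70% of
the variation in the environmental variables, and that of the community
model's explained variation about 73% is attributable to the local
environmental covariates, 16% to the explicit spatial random effect, and
11% to the land-use proxy itself — the environment-mediated pathway
dominates the direct land-use signal, with space in between.

The same pipeline is available from the shell:

```
streamcom simulate --seed 1 --out run/data
streamcom fit-env  --data run/data --seed 1 --out run/env
streamcom fit-jsdm --data run/data --model joint --seed 1 --out run/joint
streamcom evaluate --data run/data --fit run/joint --out run/metrics
streamcom rcp      --data run/data --seed 1 --out run/rcp
streamcom flow     --env run/env --fit run/metrics --out run/flow
```

## Layout

```
src/streamcom/
  io.py          tables, trees, taxon filters, transformations
  config.py      declarative run configuration (YAML)
  simulate.py    synthetic data with ground truth
  samplers.py    shared Gibbs primitives (truncated normal, spatial GP grids)
  jsdm.py        the probit community model and its Gibbs sampler
  env_model.py   the Gaussian environment model
  evaluation.py  psrf, Tjur R², AUC, variance partition, causal flow
  rcp.py         Jaccard / cascading K-means / Calinski clustering
  cli.py         command-line interface
docs/methods.md  model details, conventions, and limitations
```
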