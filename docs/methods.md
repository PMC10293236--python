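# Methods

This note records the models implemented in `streamcom`, the conventions
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Data model and transformations

A dataset consists of a site table (land-use class, coordinates, five
environmental variables), a binary sites × taxa occurrence matrix, a
per-taxon trait table (trophic mode: autotroph/heterotroph; domain:
bacteria/eukaryote), and one Newick phylogeny per domain.

Conductivity (µS/cm), total phosphorus (µg/l), and the N:P ratio are
right-skewed and natural-log transformed on load; pH and temperature stay
on their measurement scale. The log base is a package convention (only
"a log transform" is standard practice here); since covariates are
standardized before fitting, the base does not affect the model, only the
reported scale of raw columns.

Taxon filtering keeps taxa present at **strictly more** than the
configured number of sites (default 10 out of 120) and can drop taxa by
taxonomic label (e.g. chloroplast sequences, unclassified taxa). An
optional upper prevalence bound removes taxa present everywhere, whose
probit intercept is not identifiable from presence-absence data.

### Phylogenetic correlation

Under Brownian trait evolution the covariance between two tips is the
root-to-MRCA path length, so the correlation is
`C[a,b] = depth(mrca) / sqrt(depth(a) · depth(b))` with unit diagonal.
For ultrametric trees this equals shared depth over tree height.
Non-ultrametric trees are accepted — each root-to-tip path is effectively
rescaled to 1 — with a warning when tip depths disagree by more than 1%.
The construction is a valid correlation matrix (positive semi-definite);
eigenvalues are clipped at zero before use.

## The community model

Occurrence is Bernoulli-probit with unit residual variance (the standard
identifiability convention for multivariate probit):

    y_ij = 1{z_ij > 0},   z_ij = x_i β_j + Σ_h η_ih λ_hj + ε_ij,  ε ~ N(0,1)

* `x_i`: intercept, land-use indicator (0/1), and the five continuous
  covariates centered and scaled to unit variance (p = 7). Standardizing
  the continuous covariates is a package convention; it makes effect
  sizes comparable and the priors meaningful.
* Niche coefficients: `B ~ MN(Γ Tᵀ, V, ρC + (1−ρ)I)` — trait-predicted
  means, covariance `V` among covariates, and an among-taxa correlation
  mixing the phylogeny `C` with independence via the weight `ρ`.
* Trait design `T`: intercept + trophy indicator; the cross-domain
  ("joint") model, which cannot use a single tree, instead adds the
  domain indicator and the trophy × domain interaction (and omits `C`).
* Spatial random effect: `n_f` latent factors (default 2) with
  Gaussian-process priors `exp(−d/α_h)` over site coordinates and
  standard-normal loadings. No adaptive factor shrinkage is used; the
  number of factors is a configuration knob.

### Priors and grids

* `Γ` ~ N(0, 10²) elementwise; `V` ~ inverse-Wishart(p + 2, I).
* `ρ`: uniform prior on a grid of 101 equally spaced points on [0, 1].
* `α_h`: uniform prior on a grid of 11 values from 0 (spatially
  unstructured) to the landscape diagonal.

### Gibbs sampler

Fixed update order per iteration: (1) latent `z` from truncated normals;
(2) `B` jointly; (3) `Γ`; (4) `V`; (5) `ρ` from its discrete grid
posterior; (6) factor scores `η`; (7) loadings `Λ`; (8) each `α_h` from
its grid posterior. Iteration `t` (1-based) is retained when
`t > burn_in` and `(t − burn_in) mod thin = 0`, giving exactly
`⌊(n_iterations − burn_in)/thin⌋` draws per chain; chain `k` uses seed
`seed + k`. The default schedule is 4 chains × 37,500 iterations,
burn-in 12,500, thinning 100 (250 draws per chain, 1,000 per model).

Two implementation details matter for efficiency and robustness:

* **Eigen-rotation of the among-taxa covariance.** `ρC + (1−ρ)I` shares
  the eigenvectors of `C` for every `ρ`, and the probit residuals are
  i.i.d., so rotating the latent residuals by the eigenvectors decouples
  taxa: the joint `B` update reduces to one p × p solve per taxon, and
  the `ρ` grid likelihood to an O(grid × taxa) evaluation. With no
  phylogeny all columns share one factorization. A zero prior eigenvalue
  (possible at ρ = 1) collapses that component onto its prior mean.
* **Truncated-normal draws** use the inverse CDF evaluated in the smaller
  tail (means clipped at ±37 sd, probabilities floored at 1e−300), so
  extreme linear predictors stay finite with the correct sign.

Degenerate conditional covariances raise a numerical-stability error
carrying the iteration index. Checkpoint/resume of interrupted chains is
not implemented.

Prediction averages the probit probability over retained draws
(`mean_s Φ(lp^(s))`, not `Φ(mean lp)`). Because factor scores exist only
at training sites, prediction at new sites is refused whenever the model
has spatial factors.

## The environment model

The five (standardized) environmental variables are responses in a
Gaussian identity-link model: land use as fixed effect, the same spatial
latent-factor random effect shared across responses, and
response-specific residual variances with inverse-gamma(0.1, 0.1) priors;
coefficients have N(0, 10²) priors on the standardized scale.
Standardizing responses internally and reporting R² (which is
scale-invariant) is a package convention.

R² is computed from posterior-mean predictions — fitted values averaged
over draws — which is invariant to the sign/rotation indeterminacy of the
latent factors. The explained variance is split between the fixed and
latent fitted components in proportion to their variances; the land-use
and spatial shares are also re-expressed on the total-variance scale.
Responses whose model explains essentially nothing get NaN fractions by
construction (an explicit "undefined" marker, not failed arithmetic).

## Variance partitioning and the causal flow

Per draw and taxon, the fixed-effect variance attributed to covariate
group *g* is `Σ_{k∈g} β_k (S β)_k` with `S` the empirical covariance
(denominator n) of the realized design matrix — within-group terms in
full plus exactly half of each cross-group covariance term (an explicit
convention for splitting covariance between correlated groups, e.g. land
use and conductivity). The random-effect variance is the **empirical
variance across sites of the realized latent term** `η λ_j`. The more
common shorthand `Σ_h λ_hj²` assumes factor scores with unit marginal
variance, but the scale split between scores and loadings is only weakly
identified (long spatial ranges make the GP kernel nearly singular, with
scores shrinking and loadings inflating), and the realized-term variance
is invariant to that split. Small negative cross-covariance remainders
are clipped to zero before normalizing fractions per draw; fractions are
then averaged over draws. Community means are unweighted across taxa.

The causal-flow summary combines (i) the mean environment-model R² — the
average share of environmental variation explained by land use plus
location — with (ii) the community-model partition aggregated into three
shares (environmental covariates, land-use proxy, spatial random effect),
rescaled to sum to 100%.

Response support: a coefficient is *supported* at level q (default 0.90)
when at least q of its posterior draws share one sign; the boundary
counts as supported. Summaries are reported for the four trophy × domain
groups.

Convergence: the Gelman-Rubin psrf is computed per scalar parameter on
retained draws, without chain splitting (`sqrt(((N−1)/N·W + B/N)/W)`);
a split-chain variant can be obtained by passing each half chain
separately. Tjur R² is the mean predicted probability at presences minus
at absences; AUC counts concordant presence/absence pairs with ties at
one half.

## RCP clustering

Dissimilarity between sites is the square-root binary Jaccard
`d = sqrt(1 − a/(a+b+c))` (the Euclidean-embeddable convention of the
classical binary-distance implementations; plain `1 − S` is available
behind a flag). K-means is run on the **rows of the dissimilarity
matrix** as feature vectors — the faithful emulation of chaining a
dissimilarity computation into a K-means routine that consumes a data
matrix — with a PCoA-embedding alternative behind a flag. For each K in
1..10 the best of 1,000 uniformly random restarts (lowest within-cluster
sum of squares, each restart capped at 300 Lloyd iterations) is kept; the
Calinski-Harabasz criterion `[SSB/(K−1)]/[SSW/(n−K)]` selects K over
K ≥ 2 (undefined at K = 1 and K = n). RCPs are renumbered so RCP 1 has
the highest agricultural proportion.

## The synthetic-data generator

The generator emulates the processed layout of the motivating field
study: 120 sites split 60/60 between agricultural and forested classes on
a unit square, 217 taxa (58 bacteria, 159 eukaryotes), one pure-birth
ultrametric phylogeny per domain (height 1), and a trait table with a
45% autotroph fraction.

Each environmental variable (on its modelling scale) is a standardized
sum of a land-use component, a spatial component, and independent noise
with configurable variance fractions. The defaults follow the study's
reported pattern — land use dominating conductivity (0.79) and pH
(0.58), space dominating the N:P ratio (0.64) and sharing total
phosphorus with land use (0.52/0.43), temperature essentially
unexplained. The spatial component of every variable is a unit-norm
mixture of two shared latent GP fields (ranges: a quarter of the
landscape diagonal, and half that) — spatial structure in stream
chemistry is shared across variables, and this is also the structure the
model's spatial factors assume. Raw-scale means and spreads (e.g. median
conductivity ≈ 245 µS/cm, pH ≈ 7.6 ± 0.45) are chosen as realistic for
temperate lowland streams; agriculture raises conductivity, pH, and
phosphorus and lowers the N:P ratio.

Communities are drawn from the model itself: `B` from the matrix-normal
prior at the true `Γ`, `V = 0.2² I`, `ρ = 0.7`, and a block-diagonal `C`
(per-domain trees, no cross-domain correlation); two spatial factors with
loading sd 0.35; occurrences from the probit layer. The default `Γ` is
chosen to qualitatively reproduce the study's response patterns
(autotrophic bacteria favoured by agriculture and high pH, heterotrophs
disfavoured by nutrients, autotrophic eukaryotes responding positively to
phosphorus, heterotrophic eukaryotes mostly negative) — these effect
sizes are synthetic conventions, not measured values. Under these
defaults the expected community-variance shares order environment
(~0.65) > spatial (~0.25) > direct land-use (~0.05), mirroring the
study's qualitative headline.

What the generator does **not** emulate: sequence-level noise and OTU
clustering artefacts, abundance information, imbalanced or clustered
sampling designs, non-exponential spatial kernels, trait measurement
error, or reticulate/non-ultrametric phylogenies. Passing recovery tests
on this generator shows the estimation machinery is correct under the
model's own assumptions; it does not certify robustness to model
misspecification in field data.

## Problem sizes used in validation

Routine tests use ~30–60 sites and ~8–30 taxa with short chains. The
validation suite fits the reduced-scale recovery model (40 sites × 30
taxa, 2 chains × 5,000 iterations), matches the printed retained-draw
arithmetic with the full 4 × 37,500 schedule on a minimal model, and runs
one full-size fit (120 × 217, 2 chains × 4,000 iterations) for the
causal-flow ordering; these sizes are the package's chosen trade-off
between Monte-Carlo stability and runtime.

## Known limitations

* No spatial prediction (kriging) to unsampled sites; no abundance
  models; no variable selection.
* The number of latent factors is fixed per fit (no adaptive shrinkage),
  and loadings mix more slowly than niche coefficients; convergence
  checks focus on `B`, which is what downstream summaries use.
* The ρ grid bounds resolution of the phylogenetic weight to 0.01.
* `V` is sampled with an inverse-Wishart conditional, which couples
  variances and correlations in the usual way.
* Cross-group covariance splitting and negative-remainder clipping make
  the variance partition a reporting convention, not a unique
  decomposition, when covariates are strongly collinear.
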