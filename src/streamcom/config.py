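"""Run configuration: MCMC schedule, grids, priors, clustering settings.

A single :class:`RunConfig` drives every stage of the pipeline and can be
round-tripped through a YAML file, so a whole analysis is reproducible
from one declarative document plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

__all__ = ["MCMCSchedule", "RunConfig"]


@dataclass
class MCMCSchedule:
    """Gibbs sampling schedule.

    Defaults follow the study protocol: four chains of 37,500 iterations,
    the first 12,500 discarded as burn-in, thinning of 100, yielding 250
    retained draws per chain (1,000 per model).
    """

    n_chains: int = 4
    n_iterations: int = 37_500
    burn_in: int = 12_500
    thin: int = 100

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        """Number of retained draws per chain: floor((n_iterations - burn_in) / thin)."""
        return (self.n_iterations - self.burn_in) // self.thin

    @property
    def n_retained_total(self) -> int:
        return self.n_chains * self.n_retained_per_chain


@dataclass
class RunConfig:
    """Configuration shared by simulation, model fitting, and clustering."""

    mcmc: MCMCSchedule = field(default_factory=MCMCSchedule)
    seed: int = 0

    # hierarchical community model
    n_factors: int = 2              #: number of spatial latent factors
    rho_grid_size: int = 101        #: grid resolution for the phylogenetic weight on [0, 1]
    alpha_grid_size: int = 11       #: grid resolution for the spatial range (0 .. landscape diagonal)
    gamma_prior_sd: float = 10.0    #: sd of the normal prior on trait-to-niche coefficients
    coef_prior_sd: float = 10.0     #: sd of the normal prior on environment-model coefficients
    resid_prior_shape: float = 0.1  #: inverse-gamma shape for residual variances (environment model)
    resid_prior_rate: float = 0.1   #: inverse-gamma rate for residual variances (environment model)

    # community classification
    k_min: int = 1                  #: smallest number of clusters tried
    k_max: int = 10                 #: largest number of clusters tried
    n_restarts: int = 1000          #: random K-means restarts per K (best within-cluster SS kept)

    # filtering and reporting
    prevalence_threshold: int = 10  #: keep taxa present at strictly more sites than this
    support_level: float = 0.90     #: posterior probability defining a supported response

    def __post_init__(self):
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCSchedule(**self.mcmc)
        if self.rho_grid_size < 2 or self.alpha_grid_size < 2:
            raise ValueError("grid sizes must be >= 2")
        if not 0.5 < self.support_level < 1:
            raise ValueError("support_level must lie in (0.5, 1)")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
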