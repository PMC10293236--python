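"""Shared fixtures: small synthetic datasets built at test time."""

from dataclasses import replace

import numpy as np
import pytest

from streamcom.config import MCMCSchedule, RunConfig
from streamcom.io import correlation_from_tree, filter_taxa
from streamcom.jsdm import design_matrix
from streamcom.simulate import (
    default_ground_truth,
    generate_community,
    generate_landscape,
    generate_phylogeny,
    generate_traits,
)


def single_domain_dataset(n_sites=40, n_taxa=30, seed=1, rho_true=0.7,
                          n_factors=2):
    """One-domain (bacterial) community with a phylogeny and ground truth,
    filtered so that every taxon has at least one presence and one absence."""
    sites = generate_landscape(n_sites=n_sites, seed=seed)
    ids = [f"b{i + 1:04d}" for i in range(n_taxa)]
    tree = generate_phylogeny(n_taxa, seed=seed + 1, labels=ids)
    C = correlation_from_tree(tree, ids)
    traits = generate_traits(ids, ["bacteria"] * n_taxa, seed=seed + 2)
    _, cov_names, _, _ = design_matrix(sites)
    truth = replace(default_ground_truth(cov_names,
                                         ["intercept", "trophy_heterotroph"]),
                    rho_true=rho_true)
    cm, realized = generate_community(sites, C, traits, truth, seed=seed + 3,
                                      n_factors=n_factors)
    keep = (cm.prevalence() > 0) & (cm.prevalence() < cm.n_sites)
    cm_f = filter_taxa(cm, min_prevalence=0, max_prevalence=cm.n_sites - 1)
    mask = np.isin(cm.taxa, cm_f.taxa)
    return {
        "sites": sites,
        "community": cm_f,
        "traits": traits.loc[cm_f.taxa],
        "C": C[np.ix_(mask, mask)],
        "tree": tree,
        "beta_true": realized.Beta[:, mask],
        "truth": realized,
    }


@pytest.fixture(scope="session")
def small_dataset():
    return single_domain_dataset()


def short_schedule(n_chains=2, n_iterations=1000, burn_in=400, thin=2,
                   **kwargs) -> RunConfig:
    return RunConfig(mcmc=MCMCSchedule(n_chains=n_chains,
                                       n_iterations=n_iterations,
                                       burn_in=burn_in, thin=thin), **kwargs)
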