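"""Model diagnostics, fit metrics, variance partitioning, and the
land-use → environment → community causal-flow summary.

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor on retained (post-burn-in, thinned) draws. Discriminatory power of
the presence-absence models uses Tjur's coefficient of discrimination and
the area under the ROC curve. Explained variance per taxon is partitioned
among covariate groups and the spatial random effect following the
standard community-modelling decomposition: fixed-effect variance from
the empirical covariance of the realized design matrix and the draw's
niche coefficients, random-effect variance from the squared loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .io import CommunityMatrix
from .jsdm import ModelSpec, PosteriorSamples

__all__ = [
    "psrf",
    "psrf_table",
    "tjur_r2",
    "auc",
    "VariancePartition",
    "variance_partition",
    "CausalFlow",
    "causal_flow",
    "supported_effects",
    "DEFAULT_GROUPS",
]

#: default covariate grouping: land use and each environmental variable
#: form their own group.
DEFAULT_GROUPS = {
    "land_use": ["land_use_agri"],
    "conductivity": ["log_conductivity"],
    "ph": ["ph"],
    "temperature": ["temperature"],
    "total_phosphorus": ["log_total_phosphorus"],
    "np_ratio": ["log_np_ratio"],
}

#: groups that represent local environmental conditions (everything except
#: the land-use proxy)
ENVIRONMENT_GROUPS = ["conductivity", "ph", "temperature",
                      "total_phosphorus", "np_ratio"]


def psrf(chains: np.ndarray, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor of one scalar parameter.

    ``chains`` is (n_chains, n_draws). With W the mean within-chain
    variance and B/N the variance of the chain means, the statistic is
    ``sqrt(((N - 1)/N * W + B/N) / W)``; identical chains give
    ``sqrt((N - 1)/N)`` and diverged chains values well above 1.
    ``split=True`` halves each chain first (the split-chain variant,
    sensitive to within-chain trends).
    """
    chains = np.asarray(chains, dtype=float)
    if split:
        half = chains.shape[1] // 2
        chains = np.concatenate([chains[:, :half], chains[:, half:2 * half]])
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains of equal length")
    m, n = chains.shape
    if n < 4:
        raise ValueError("chains too short for a meaningful psrf")
    W = chains.var(axis=1, ddof=1).mean()
    if W <= 0:
        raise ValueError("zero within-chain variance; degenerate chains")
    B_over_n = chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B_over_n) / W))


def psrf_table(post: PosteriorSamples, block: str = "beta") -> np.ndarray:
    """psrf of every scalar parameter in one posterior block (flattened)."""
    arr = post.by_chain(block)  # (n_chains, n_per_chain, ...)
    flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
    return np.array([psrf(flat[:, :, i]) for i in range(flat.shape[2])])


def _check_binary(y, p):
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("y contains a single class; metric undefined")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return y, p


def tjur_r2(y, p) -> float:
    """Tjur's coefficient of discrimination: mean predicted probability at
    presences minus mean predicted probability at absences."""
    y, p = _check_binary(y, p)
    return float(p[y == 1].mean() - p[y == 0].mean())


def auc(y, p) -> float:
    """Area under the ROC curve: probability that a random presence scores
    higher than a random absence, ties counting one half."""
    y, p = _check_binary(y, p)
    return float(roc_auc_score(y, p))


def fit_metrics(cm: CommunityMatrix, prob: np.ndarray) -> pd.DataFrame:
    """Per-taxon Tjur R² and AUC for a fitted presence-absence model."""
    rows = []
    for j, taxon in enumerate(cm.taxa):
        y = cm.occurrence[:, j]
        rows.append({"taxon": taxon,
                     "tjur_r2": tjur_r2(y, prob[:, j]),
                     "auc": auc(y, prob[:, j])})
    return pd.DataFrame(rows)


@dataclass
class VariancePartition:
    """Per-taxon explained-variance fractions by covariate group and by the
    spatial random effect, plus their community (unweighted) means."""

    fractions: pd.DataFrame           # taxa x (groups + 'spatial')
    community_means: pd.Series
    sites: tuple = field(default_factory=tuple)


def variance_partition(spec: ModelSpec, post: PosteriorSamples,
                       groups: dict | None = None) -> VariancePartition:
    """Partition each taxon's explained variance among covariate groups and
    the spatial random effect.

    Per draw and taxon, the fixed-effect variance assigned to group ``g``
    is ``sum_{k in g} beta_k (S beta)_k`` with ``S`` the empirical
    covariance (denominator n) of the design matrix — within-group terms
    in full plus exactly half of every cross-group covariance term. The
    random-effect variance is the empirical variance across sites of the
    realized latent term ``eta lambda_j``; unlike the sum of squared
    loadings this is invariant to the scale split between factor scores
    and loadings, which is only weakly identified. Fractions are
    normalized per draw (tiny negative cross-covariance remainders are
    clipped to zero) and averaged over draws.
    """
    groups = groups or DEFAULT_GROUPS
    names = spec.covariate_names
    covered = [c for g in groups.values() for c in g]
    missing = [c for c in names if c != "intercept" and c not in covered]
    if missing:
        raise ValueError(f"covariate grouping does not cover: {missing}")
    unknown = [c for c in covered if c not in names]
    if unknown:
        raise ValueError(f"grouping refers to unknown covariates: {unknown}")

    S = np.cov(spec.X, rowvar=False, ddof=0)
    idx = {g: [names.index(c) for c in cols] for g, cols in groups.items()}
    group_names = list(groups) + ["spatial"]
    n_taxa = spec.n_taxa
    acc = np.zeros((n_taxa, len(group_names)))
    for s in range(post.n_draws):
        B = post.beta[s]                     # p x n_taxa
        SB = S @ B
        contrib = np.empty((n_taxa, len(group_names)))
        for gi, g in enumerate(groups):
            rows = idx[g]
            contrib[:, gi] = (B[rows] * SB[rows]).sum(axis=0)
        if post.lam.shape[1]:
            latent = post.eta[s] @ post.lam[s]        # n_sites x n_taxa
            contrib[:, -1] = latent.var(axis=0)
        else:
            contrib[:, -1] = 0.0
        contrib = np.clip(contrib, 0.0, None)
        total = contrib.sum(axis=1)
        total[total == 0] = 1.0
        acc += contrib / total[:, None]
    frac = pd.DataFrame(acc / post.n_draws, index=spec.taxa, columns=group_names)
    return VariancePartition(fractions=frac,
                             community_means=frac.mean(axis=0),
                             sites=tuple(spec.sites))


@dataclass
class CausalFlow:
    """Aggregated land-use → environment → community flow summary.

    ``env_mean_r2_pct`` is the mean share (percent) of environmental
    variation explained by land use plus location; ``community_shares``
    splits the community model's explained variation among the
    environmental covariates, the land-use proxy, and the spatial random
    effect, rescaled to sum to 100.
    """

    env_mean_r2_pct: float
    community_shares: dict


def causal_flow(env_part: pd.DataFrame, vp: VariancePartition) -> CausalFlow:
    """Combine the environment-model partition and the community-model
    partition into the causal-flow summary."""
    env_sites = env_part.attrs.get("sites")
    if env_sites is not None and vp.sites and tuple(env_sites) != tuple(vp.sites):
        raise ValueError("environment and community fits used different sites")
    env_mean = float(np.nan_to_num(env_part["r2"], nan=0.0).mean()) * 100.0
    means = vp.community_means
    env_share = float(means.reindex(ENVIRONMENT_GROUPS).fillna(0.0).sum())
    lu_share = float(means.get("land_use", 0.0))
    sp_share = float(means.get("spatial", 0.0))
    total = env_share + lu_share + sp_share
    if total <= 0:
        shares = {"environment": 0.0, "land_use": 0.0, "spatial": 0.0}
    else:
        shares = {"environment": 100.0 * env_share / total,
                  "land_use": 100.0 * lu_share / total,
                  "spatial": 100.0 * sp_share / total}
    return CausalFlow(env_mean_r2_pct=env_mean, community_shares=shares)


def supported_effects(spec: ModelSpec, post: PosteriorSamples,
                      traits: pd.DataFrame, level: float = 0.90):
    """Taxon-level environmental responses with posterior-probability support.

    A response is *supported* when at least ``level`` of the posterior
    draws of the coefficient share one sign (the boundary counts as
    supported). Returns ``(effects, group_summary)``: the per-taxon table
    of posterior-mean standardized effects with support flags, and counts
    of supported responses per trophy x domain group.
    """
    if not 0.5 < level < 1:
        raise ValueError("support level must lie in (0.5, 1)")
    traits = traits.loc[list(spec.taxa)]
    rows = []
    for k, cov in enumerate(spec.covariate_names):
        if cov == "intercept":
            continue
        draws = post.beta[:, k, :]            # (n_draws, n_taxa)
        p_pos = (draws > 0).mean(axis=0)
        mean = draws.mean(axis=0)
        for j, taxon in enumerate(spec.taxa):
            supported = p_pos[j] >= level or (1.0 - p_pos[j]) >= level
            rows.append({
                "taxon": taxon, "covariate": cov, "effect": mean[j],
                "sign": "+" if mean[j] >= 0 else "-",
                "supported": bool(supported),
                "trophy": traits.loc[taxon, "trophy"],
                "domain": traits.loc[taxon, "domain"],
            })
    effects = pd.DataFrame(rows)
    grp = (effects[effects["supported"]]
           .groupby(["trophy", "domain"], observed=True)
           .size().rename("n_supported").reset_index())
    return effects, grp
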