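"""Hierarchical joint species distribution model with a bespoke Gibbs sampler.

The model is the multivariate probit variant of hierarchical community
modelling (HMSC-style). For site ``i`` and taxon ``j``,

.. math::

    y_{ij} = 1\\{z_{ij} > 0\\}, \\qquad
    z_{ij} = x_i \\beta_j + \\sum_h \\eta_{ih} \\lambda_{hj} + \\varepsilon_{ij},
    \\qquad \\varepsilon_{ij} \\sim N(0, 1),

where ``x_i`` holds the intercept, the land-use indicator, and the five
standardized environmental covariates. Taxon niches are structured by
traits and phylogeny through a matrix-normal prior

.. math::

    B \\sim MN(\\Gamma T^\\top,\\; V,\\; \\rho C + (1 - \\rho) I),

with ``T`` the trait design matrix (trophic mode, and domain for the
cross-domain model), ``V`` the niche covariance among covariates, ``C``
the phylogenetic correlation matrix, and ``rho`` in [0, 1] the weight of
the phylogenetic structure (0 = independent residual niches, 1 = fully
phylogenetically structured). The spatial random effect is a set of
latent factors with Gaussian-process priors ``exp(-d / alpha_h)`` over
site coordinates.

All full conditionals are available in closed form except ``rho`` and the
spatial ranges ``alpha_h``, which are sampled from discrete grid
posteriors. The among-taxa covariance is handled through a single
eigendecomposition ``C = U D U^T``: because ``rho C + (1 - rho) I`` shares
the eigenvectors ``U`` for every ``rho``, rotating the latent residuals by
``U`` decouples the taxa and reduces the joint niche update to one small
solve per taxon.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.special import ndtr
from scipy.stats import invwishart

from .config import MCMCSchedule, RunConfig
from .io import CommunityMatrix
from .samplers import (
    SpatialGrid,
    draw_factor_scores,
    draw_loadings,
    draw_alpha_index,
    draw_truncated_probit,
    sample_log_weights,
)

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "design_matrix",
    "trait_design",
    "build_model_spec",
    "gibbs_sample",
    "predict_probability",
    "estimate_rho_summary",
]

CONTINUOUS_COVARIATES = [
    "log_conductivity",
    "ph",
    "temperature",
    "log_total_phosphorus",
    "log_np_ratio",
]


def design_matrix(sites: pd.DataFrame):
    """Site-level covariate matrix: intercept, land-use indicator, and the
    five continuous covariates centered and scaled to unit variance.

    Returns ``(X, names, means, sds)``; the standardization constants are
    kept so that the same mapping can be applied to new tables.
    """
    n = len(sites)
    cols = [np.ones(n), (sites["land_use"] == "agricultural").to_numpy(float)]
    names = ["intercept", "land_use_agri"]
    means, sds = {}, {}
    for c in CONTINUOUS_COVARIATES:
        if c not in sites.columns:
            raise KeyError(f"site table lacks covariate {c!r}; "
                           "was it read with transform=True?")
        v = sites[c].to_numpy(float)
        mu, sd = v.mean(), v.std()
        if sd == 0:
            raise ValueError(f"covariate {c!r} is constant")
        cols.append((v - mu) / sd)
        names.append(c)
        means[c], sds[c] = mu, sd
    return np.column_stack(cols), names, means, sds


def trait_design(traits: pd.DataFrame, include_domain: bool):
    """Taxon-level trait design: intercept + trophy indicator, plus domain
    indicator and its interaction with trophy for the cross-domain model."""
    het = (traits["trophy"] == "heterotroph").to_numpy(float)
    cols = [np.ones(len(traits)), het]
    names = ["intercept", "trophy_heterotroph"]
    if include_domain and traits["domain"].nunique() > 1:
        euk = (traits["domain"] == "eukaryote").to_numpy(float)
        cols += [euk, het * euk]
        names += ["domain_eukaryote", "heterotroph_x_eukaryote"]
    return np.column_stack(cols), names


@dataclass
class ModelSpec:
    """Frozen definition of one model fit: data-dependent matrices, grids,
    and prior hyperparameters."""

    X: np.ndarray
    covariate_names: list
    cov_means: dict
    cov_sds: dict
    T: np.ndarray
    trait_names: list
    C: np.ndarray | None
    coords: np.ndarray
    sites: list
    taxa: list
    n_factors: int
    rho_grid: np.ndarray
    alpha_grid: np.ndarray
    gamma_prior_sd: float = 10.0
    #: eigendecomposition of C (computed on construction when C is given)
    U: np.ndarray | None = field(default=None, repr=False)
    d: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.C is not None:
            dd, U = np.linalg.eigh(self.C)
            self.d = np.clip(dd, 0.0, None)
            self.U = U

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.T.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for a in (self.X, self.T, self.coords,
                  self.C if self.C is not None else np.zeros(1)):
            h.update(np.ascontiguousarray(a, dtype=float).tobytes())
        h.update(",".join(self.covariate_names + self.trait_names).encode())
        h.update(f"{self.n_factors}|{len(self.rho_grid)}|{len(self.alpha_grid)}".encode())
        return h.hexdigest()[:16]


def build_model_spec(sites: pd.DataFrame, cm: CommunityMatrix,
                     traits: pd.DataFrame, C: np.ndarray | None = None,
                     config: RunConfig | None = None) -> ModelSpec:
    """Assemble a :class:`ModelSpec` from validated inputs.

    The trait design includes the domain terms only when no phylogeny is
    supplied (the cross-domain model cannot use a single tree). Taxa that
    are absent everywhere or present everywhere are rejected: their probit
    intercept is not identifiable from presence-absence data.
    """
    config = config or RunConfig()
    if list(cm.sites) != list(sites["site_id"]):
        raise ValueError("community matrix site order does not match site table")
    prev = cm.prevalence()
    degenerate = [t for t, p in zip(cm.taxa, prev)
                  if p == 0 or p == cm.n_sites]
    if degenerate:
        raise ValueError(
            f"taxa with zero or full prevalence: {degenerate}; "
            "filter them out before fitting"
        )
    traits = traits.loc[list(cm.taxa)]
    X, names, means, sds = design_matrix(sites)
    T, tnames = trait_design(traits, include_domain=C is None)
    if C is not None:
        C = np.asarray(C, dtype=float)
        if C.shape != (cm.n_taxa, cm.n_taxa):
            raise ValueError("phylogenetic correlation shape mismatch")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("phylogenetic correlation must have unit diagonal")
    coords = sites[["longitude", "latitude"]].to_numpy(float)
    span = coords.max(axis=0) - coords.min(axis=0)
    diag = float(np.sqrt((span ** 2).sum())) or 1.0
    return ModelSpec(
        X=X, covariate_names=names, cov_means=means, cov_sds=sds,
        T=T, trait_names=tnames, C=C, coords=coords,
        sites=list(cm.sites), taxa=list(cm.taxa),
        n_factors=config.n_factors,
        rho_grid=np.linspace(0.0, 1.0, config.rho_grid_size),
        alpha_grid=np.linspace(0.0, diag, config.alpha_grid_size),
        gamma_prior_sd=config.gamma_prior_sd,
    )


@dataclass
class PosteriorSamples:
    """Retained draws of every parameter block, concatenated across chains.

    Chain ``k`` of the fit used seed ``seed + k``; the ``chain`` vector
    records provenance so chains can be separated again for convergence
    diagnostics.
    """

    beta: np.ndarray      # (n_draws, p, n_taxa)
    gamma: np.ndarray     # (n_draws, p, q)
    V: np.ndarray         # (n_draws, p, p)
    rho: np.ndarray       # (n_draws,)
    eta: np.ndarray       # (n_draws, n_sites, n_factors)
    lam: np.ndarray       # (n_draws, n_factors, n_taxa)
    alpha: np.ndarray     # (n_draws, n_factors)
    chain: np.ndarray     # (n_draws,)
    schedule: MCMCSchedule
    spec_fingerprint: str = ""
    has_phylogeny: bool = False

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain.max()) + 1 if self.n_draws else 0

    def sign_fixed_loadings(self):
        """Loadings and factor scores with the per-draw sign indeterminacy
        removed: the first loading of largest magnitude per factor is made
        positive (draw-level rotation is left free). Returns (eta, lam)."""
        eta = self.eta.copy()
        lam = self.lam.copy()
        for s in range(self.n_draws):
            for h in range(lam.shape[1]):
                row = lam[s, h]
                if row.size and row[np.argmax(np.abs(row))] < 0:
                    lam[s, h] = -row
                    eta[s, :, h] = -eta[s, :, h]
        return eta, lam

    def by_chain(self, name: str) -> np.ndarray:
        """Stack draws of one block as (n_chains, n_per_chain, ...)."""
        arr = getattr(self, name)
        chains = [arr[self.chain == k] for k in range(self.n_chains)]
        return np.stack(chains)

    def save(self, path) -> None:
        np.savez_compressed(
            path, beta=self.beta, gamma=self.gamma, V=self.V, rho=self.rho,
            eta=self.eta, lam=self.lam, alpha=self.alpha, chain=self.chain,
            schedule=np.array([self.schedule.n_chains, self.schedule.n_iterations,
                               self.schedule.burn_in, self.schedule.thin]),
            fingerprint=np.array([self.spec_fingerprint]),
            has_phylogeny=np.array([self.has_phylogeny]),
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as f:
            sched = f["schedule"]
            return cls(
                beta=f["beta"], gamma=f["gamma"], V=f["V"], rho=f["rho"],
                eta=f["eta"], lam=f["lam"], alpha=f["alpha"], chain=f["chain"],
                schedule=MCMCSchedule(*[int(v) for v in sched]),
                spec_fingerprint=str(f["fingerprint"][0]),
                has_phylogeny=bool(f["has_phylogeny"][0]),
            )


def _beta_conditional(E_rot, X, XtX, M_rot, Vinv, drho):
    """Per-taxon conditional moments of the rotated niche coefficients.

    Returns a list of (mean, chol_precision) per rotated taxon column; a
    zero prior eigenvalue collapses the conditional onto the prior mean.
    """
    out = []
    XtE = X.T @ E_rot
    for j in range(E_rot.shape[1]):
        dj = drho[j]
        if dj < 1e-12:
            out.append((M_rot[:, j], None))
            continue
        Q = XtX + Vinv / dj
        L = cholesky(Q, lower=True)
        mean = cho_solve((L, True), XtE[:, j] + (Vinv @ M_rot[:, j]) / dj)
        out.append((mean, L))
    return out


def _draw_beta(rng, E, X, XtX, M, Vinv, rho, U, d):
    """Joint matrix-normal update of B given latent residuals ``E``."""
    p, n = M.shape
    if U is None:
        # no phylogeny: columns are exchangeable, one shared factorization
        Q = XtX + Vinv
        L = cholesky(Q, lower=True)
        mean = cho_solve((L, True), X.T @ E + Vinv @ M)
        noise = solve_triangular(L.T, rng.standard_normal((p, n)), lower=False)
        return mean + noise
    drho = rho * d + (1.0 - rho)
    E_rot, M_rot = E @ U, M @ U
    B_rot = np.empty((p, n))
    for j, (mean, L) in enumerate(_beta_conditional(E_rot, X, XtX, M_rot, Vinv, drho)):
        if L is None:
            B_rot[:, j] = mean
        else:
            B_rot[:, j] = mean + solve_triangular(
                L.T, rng.standard_normal(p), lower=False)
    return B_rot @ U.T


def _draw_gamma(rng, B_rot, T_rot, drho, Vinv, prior_sd):
    """Conditional update of the trait-to-niche coefficients Gamma (p x q)."""
    p = Vinv.shape[0]
    q = T_rot.shape[1]
    Tw = T_rot / drho[:, None]
    A = T_rot.T @ Tw
    Q = np.kron(A, Vinv) + np.eye(p * q) / prior_sd ** 2
    rhs = (Vinv @ (B_rot @ Tw)).ravel(order="F")
    L = cholesky(Q, lower=True)
    mean = cho_solve((L, True), rhs)
    noise = solve_triangular(L.T, rng.standard_normal(p * q), lower=False)
    return (mean + noise).reshape((p, q), order="F")


def _draw_v(rng, R_rot, drho, p):
    """Inverse-Wishart conditional for the niche covariance V."""
    S = (R_rot / drho[None, :]) @ R_rot.T
    df = (p + 2) + R_rot.shape[1]
    draw = invwishart.rvs(df=df, scale=np.eye(p) + S, random_state=rng)
    return np.atleast_2d(draw)


def _rho_log_weights(R_rot, Vinv, d, rho_grid, p):
    """Log grid posterior of rho given the rotated niche residuals."""
    q = np.einsum("ij,ij->j", R_rot, Vinv @ R_rot)
    dmat = rho_grid[:, None] * d[None, :] + (1.0 - rho_grid[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        log_w = -0.5 * p * np.log(dmat).sum(axis=1) - 0.5 * (q[None, :] / dmat).sum(axis=1)
    log_w[~np.isfinite(log_w)] = -np.inf
    log_w[(dmat <= 0).any(axis=1)] = -np.inf
    return log_w


def _run_chain(spec: ModelSpec, Y: np.ndarray, schedule: MCMCSchedule,
               rng: np.random.Generator, grid: SpatialGrid,
               fix_gamma=None, fix_v=None, fix_rho=None):
    """One Gibbs chain; returns dict of retained draw arrays.

    Update order per iteration (fixed for reproducibility): latent probit
    variables z, niche coefficients B, trait coefficients Gamma, niche
    covariance V, phylogenetic weight rho, factor scores eta, loadings
    lambda, spatial ranges alpha.
    """
    n, p = spec.X.shape
    n_taxa, q = spec.T.shape
    n_f = spec.n_factors
    X, T = spec.X, spec.T
    XtX = X.T @ X
    U, d = spec.U, spec.d
    has_phylo = spec.C is not None
    T_rot = U.T @ T if has_phylo else T

    B = np.zeros((p, n_taxa))
    Gamma = np.zeros((p, q)) if fix_gamma is None else np.array(fix_gamma, float)
    V = np.eye(p) if fix_v is None else np.array(fix_v, float)
    rho = 0.0 if fix_rho is None else float(fix_rho)
    if has_phylo and fix_rho is None:
        rho = float(spec.rho_grid[len(spec.rho_grid) // 2])
    eta = 0.1 * rng.standard_normal((n, n_f)) if n_f else np.zeros((n, 0))
    lam = 0.1 * rng.standard_normal((n_f, n_taxa)) if n_f else np.zeros((0, n_taxa))
    alpha_idx = np.zeros(n_f, dtype=int)
    ones = np.ones(n_taxa)

    n_keep = schedule.n_retained_per_chain
    out = {
        "beta": np.empty((n_keep, p, n_taxa)),
        "gamma": np.empty((n_keep, p, q)),
        "V": np.empty((n_keep, p, p)),
        "rho": np.empty(n_keep),
        "eta": np.empty((n_keep, n, n_f)),
        "lam": np.empty((n_keep, n_f, n_taxa)),
        "alpha": np.empty((n_keep, n_f)),
    }
    kept = 0
    for t in range(1, schedule.n_iterations + 1):
        try:
            factor_term = eta @ lam if n_f else 0.0
            mean = X @ B + factor_term
            Z = draw_truncated_probit(rng, mean, Y)

            Vinv = np.linalg.inv(V)
            E = Z - factor_term
            M = Gamma @ T.T
            B = _draw_beta(rng, E, X, XtX, M, Vinv, rho, U, d)

            B_rot = B @ U if has_phylo else B
            drho = (rho * d + (1.0 - rho)) if has_phylo else ones
            if fix_gamma is None:
                Gamma = _draw_gamma(rng, B_rot, T_rot, drho, Vinv,
                                    spec.gamma_prior_sd)
            R_rot = B_rot - Gamma @ T_rot.T
            if fix_v is None:
                V = _draw_v(rng, R_rot, drho, p)
            if has_phylo and fix_rho is None:
                Vinv = np.linalg.inv(V)
                log_w = _rho_log_weights(R_rot, Vinv, d, spec.rho_grid, p)
                rho = float(spec.rho_grid[sample_log_weights(rng, log_w)])

            if n_f:
                W = Z - X @ B
                k_invs = [grid.inverses[a] for a in alpha_idx]
                eta = draw_factor_scores(rng, W, lam, ones, k_invs)
                lam = draw_loadings(rng, W, eta, ones)
                for h in range(n_f):
                    alpha_idx[h] = draw_alpha_index(rng, eta[:, h], grid)
        except (np.linalg.LinAlgError, FloatingPointError) as err:
            raise FloatingPointError(
                f"numerical failure in Gibbs update at iteration {t}: {err}"
            ) from err

        if t > schedule.burn_in and (t - schedule.burn_in) % schedule.thin == 0:
            out["beta"][kept] = B
            out["gamma"][kept] = Gamma
            out["V"][kept] = V
            out["rho"][kept] = rho
            out["eta"][kept] = eta
            out["lam"][kept] = lam
            out["alpha"][kept] = grid.alphas[alpha_idx] if n_f else np.empty(0)
            kept += 1
    assert kept == n_keep
    return out


def gibbs_sample(spec: ModelSpec, cm: CommunityMatrix | np.ndarray,
                 config: RunConfig, seed: int,
                 fix_gamma=None, fix_v=None, fix_rho=None) -> PosteriorSamples:
    """Fit the probit community model by Gibbs sampling.

    Parameters
    ----------
    spec
        Model definition from :func:`build_model_spec`.
    cm
        Binary occurrence data matching the spec's site and taxon order.
    config
        Carries the MCMC schedule. Chain ``k`` runs with seed
        ``seed + k``, so a fit is reproducible from ``(spec, config, seed)``.
    fix_gamma, fix_v, fix_rho
        Hold a parameter block at a fixed value instead of sampling it
        (used for oracle comparisons and prior-reproduction checks).
    """
    Y = cm.occurrence if isinstance(cm, CommunityMatrix) else np.asarray(cm)
    if Y.shape != (spec.n_sites, spec.n_taxa):
        raise ValueError("occurrence matrix does not match model spec")
    grid = SpatialGrid(spec.coords, spec.alpha_grid) if spec.n_factors else None
    blocks = []
    for k in range(config.mcmc.n_chains):
        rng = np.random.default_rng(seed + k)
        blocks.append(_run_chain(spec, Y, config.mcmc, rng, grid,
                                 fix_gamma=fix_gamma, fix_v=fix_v,
                                 fix_rho=fix_rho))
    chain_ids = np.repeat(np.arange(config.mcmc.n_chains),
                          config.mcmc.n_retained_per_chain)
    cat = {k: np.concatenate([b[k] for b in blocks]) for k in blocks[0]}
    return PosteriorSamples(
        beta=cat["beta"], gamma=cat["gamma"], V=cat["V"], rho=cat["rho"],
        eta=cat["eta"], lam=cat["lam"], alpha=cat["alpha"], chain=chain_ids,
        schedule=config.mcmc, spec_fingerprint=spec.fingerprint(),
        has_phylogeny=spec.C is not None,
    )


def predict_probability(spec: ModelSpec, post: PosteriorSamples,
                        sites: pd.DataFrame | None = None) -> np.ndarray:
    """Posterior-mean occurrence probabilities, averaged over draws.

    Probabilities are ``mean_s Phi(x_i beta_j^(s) + eta_i^(s) lambda_j^(s))``
    — the probit is applied per draw and then averaged, not applied to the
    averaged linear predictor. Prediction is restricted to the training
    sites whenever the model contains spatial factors, because the latent
    factor scores exist only there.
    """
    training = sites is None or list(sites["site_id"]) == list(spec.sites)
    if training:
        X = spec.X
    else:
        if spec.n_factors > 0:
            raise ValueError(
                "cannot predict at new sites with spatial latent factors; "
                "factor scores are only defined at training sites"
            )
        cols = [np.ones(len(sites)),
                (sites["land_use"] == "agricultural").to_numpy(float)]
        for c in CONTINUOUS_COVARIATES:
            v = sites[c].to_numpy(float)
            cols.append((v - spec.cov_means[c]) / spec.cov_sds[c])
        X = np.column_stack(cols)
    acc = np.zeros((X.shape[0], post.beta.shape[2]))
    for s in range(post.n_draws):
        lp = X @ post.beta[s]
        if spec.n_factors and training:
            lp = lp + post.eta[s] @ post.lam[s]
        acc += ndtr(lp)
    return acc / post.n_draws


def estimate_rho_summary(post: PosteriorSamples) -> tuple[float, float]:
    """Posterior mean and (population) standard deviation of rho."""
    if not post.has_phylogeny:
        raise ValueError("model was fitted without a phylogeny; rho undefined")
    return float(post.rho.mean()), float(post.rho.std())
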