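"""Gaussian environment model: how much of the local stream environment is
set by regional land use and by spatial location.

The five (transformed) environmental variables are modelled jointly with
an identity link: land-use class is the fixed effect and a spatially
explicit site-level random effect — the same latent-factor construction
as the community model, with exponential spatial covariance — absorbs
residual spatial structure shared across responses. Responses are
standardized internally and results are reported per response as an R²
plus its split into a land-use and a spatial share.

Priors: vague normals on the coefficients (sd 10 on the standardized
scale) and inverse-gamma(0.1, 0.1) on the response-specific residual
variances. R² is computed from posterior-mean predictions (fitted values
averaged over retained draws), which is invariant to the sign and
rotation indeterminacy of the latent factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, cho_solve, solve_triangular

from .config import MCMCSchedule, RunConfig
from .samplers import SpatialGrid, draw_alpha_index, draw_factor_scores, draw_loadings

__all__ = ["EnvPosterior", "fit_env_model", "env_variance_partition", "ENV_RESPONSES"]

ENV_RESPONSES = [
    "log_conductivity",
    "ph",
    "temperature",
    "log_total_phosphorus",
    "log_np_ratio",
]


@dataclass
class EnvPosterior:
    """Posterior draws of the environment model (standardized responses)."""

    coef: np.ndarray        # (n_draws, 2, n_responses): intercept, land-use
    resid_var: np.ndarray   # (n_draws, n_responses)
    eta: np.ndarray         # (n_draws, n_sites, n_factors)
    lam: np.ndarray         # (n_draws, n_factors, n_responses)
    alpha: np.ndarray       # (n_draws, n_factors)
    chain: np.ndarray
    responses: list
    sites: list
    X: np.ndarray           # (n_sites, 2) intercept + land-use indicator
    y_std: np.ndarray       # standardized response matrix (n_sites, n_responses)
    y_mean: np.ndarray
    y_sd: np.ndarray
    schedule: MCMCSchedule

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0]

    def fitted_components(self):
        """Posterior-mean fixed and latent fitted values (standardized scale)."""
        fixed = self.X @ self.coef.mean(axis=0)
        latent = np.zeros_like(self.y_std)
        if self.eta.shape[2]:
            for s in range(self.n_draws):
                latent += self.eta[s] @ self.lam[s]
            latent /= self.n_draws
        return fixed, latent


def fit_env_model(sites: pd.DataFrame, config: RunConfig | None = None,
                  seed: int = 0, n_factors: int | None = None) -> EnvPosterior:
    """Gibbs sampler for the multivariate Gaussian environment model.

    Parameters
    ----------
    sites
        Validated site table including the log-transformed columns.
    config
        MCMC schedule, priors, and grid sizes; defaults to :class:`RunConfig`.
    n_factors
        Override the number of spatial latent factors (0 disables the
        random effect, leaving independent two-group regressions).
    """
    config = config or RunConfig()
    n_f = config.n_factors if n_factors is None else n_factors
    for lu in ("agricultural", "forested"):
        if (sites["land_use"] == lu).sum() < 2:
            raise ValueError(f"need at least 2 sites in land-use class {lu}")
    Ymat = sites[ENV_RESPONSES].to_numpy(float)
    y_mean, y_sd = Ymat.mean(axis=0), Ymat.std(axis=0)
    if (y_sd == 0).any():
        const = [r for r, s in zip(ENV_RESPONSES, y_sd) if s == 0]
        raise ValueError(f"constant response column(s): {const}")
    Y = (Ymat - y_mean) / y_sd
    n, r = Y.shape
    X = np.column_stack([np.ones(n),
                         (sites["land_use"] == "agricultural").to_numpy(float)])
    XtX = X.T @ X
    coords = sites[["longitude", "latitude"]].to_numpy(float)
    grid = SpatialGrid.from_landscape(coords, config.alpha_grid_size) if n_f else None

    prior_prec = 1.0 / config.coef_prior_sd ** 2
    a0, b0 = config.resid_prior_shape, config.resid_prior_rate
    sched = config.mcmc
    n_keep = sched.n_retained_per_chain

    all_blocks = []
    for k in range(sched.n_chains):
        rng = np.random.default_rng(seed + k)
        coef = np.zeros((2, r))
        sigma2 = np.ones(r)
        eta = 0.1 * rng.standard_normal((n, n_f)) if n_f else np.zeros((n, 0))
        lam = 0.1 * rng.standard_normal((n_f, r)) if n_f else np.zeros((0, r))
        alpha_idx = np.zeros(n_f, dtype=int)
        out = {"coef": np.empty((n_keep, 2, r)),
               "resid_var": np.empty((n_keep, r)),
               "eta": np.empty((n_keep, n, n_f)),
               "lam": np.empty((n_keep, n_f, r)),
               "alpha": np.empty((n_keep, n_f))}
        kept = 0
        for t in range(1, sched.n_iterations + 1):
            latent = eta @ lam if n_f else 0.0
            # coefficients, response by response (residual variances differ)
            R0 = Y - latent
            for s in range(r):
                Q = XtX / sigma2[s] + prior_prec * np.eye(2)
                L = cholesky(Q, lower=True)
                mean = cho_solve((L, True), X.T @ R0[:, s] / sigma2[s])
                coef[:, s] = mean + solve_triangular(
                    L.T, rng.standard_normal(2), lower=False)
            resid = Y - X @ coef - latent
            sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n,
                                     1.0 / (b0 + 0.5 * (resid ** 2).sum(axis=0)))
            if n_f:
                W = Y - X @ coef
                k_invs = [grid.inverses[a] for a in alpha_idx]
                inv_nv = 1.0 / sigma2
                eta = draw_factor_scores(rng, W, lam, inv_nv, k_invs)
                lam = draw_loadings(rng, W, eta, inv_nv)
                for h in range(n_f):
                    alpha_idx[h] = draw_alpha_index(rng, eta[:, h], grid)
            if t > sched.burn_in and (t - sched.burn_in) % sched.thin == 0:
                out["coef"][kept] = coef
                out["resid_var"][kept] = sigma2
                out["eta"][kept] = eta
                out["lam"][kept] = lam
                out["alpha"][kept] = grid.alphas[alpha_idx] if n_f else np.empty(0)
                kept += 1
        all_blocks.append(out)

    cat = {k: np.concatenate([b[k] for b in all_blocks]) for k in all_blocks[0]}
    chain_ids = np.repeat(np.arange(sched.n_chains), n_keep)
    return EnvPosterior(coef=cat["coef"], resid_var=cat["resid_var"],
                        eta=cat["eta"], lam=cat["lam"], alpha=cat["alpha"],
                        chain=chain_ids, responses=list(ENV_RESPONSES),
                        sites=list(sites["site_id"]), X=X, y_std=Y,
                        y_mean=y_mean, y_sd=y_sd, schedule=sched)


def env_variance_partition(post: EnvPosterior) -> pd.DataFrame:
    """Per-response R² and its split into land-use and spatial shares.

    ``r2`` is the classical coefficient of determination of the
    posterior-mean predictions. The explained variance is split between
    the fixed (land-use) and latent (spatial) fitted components in
    proportion to their variances; ``land_use_r2`` and ``spatial_r2``
    re-express those shares on the total-variance scale. Responses whose
    model explains essentially nothing get undefined (NaN) fractions by
    construction rather than by division.
    """
    fixed, latent = post.fitted_components()
    y = post.y_std
    rows = []
    for s, resp in enumerate(post.responses):
        pred = fixed[:, s] + latent[:, s]
        ss_tot = ((y[:, s] - y[:, s].mean()) ** 2).sum()
        ss_res = ((y[:, s] - pred) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot
        v_fix = fixed[:, s].var()
        v_lat = latent[:, s].var()
        explained = v_fix + v_lat
        if explained < 1e-12 or r2 <= 0:
            f_lu = f_sp = np.nan
            r2 = max(r2, 0.0)
        else:
            f_lu = v_fix / explained
            f_sp = v_lat / explained
        rows.append({
            "response": resp, "r2": r2,
            "land_use_fraction": f_lu, "spatial_fraction": f_sp,
            "land_use_r2": r2 * f_lu if np.isfinite(f_lu) else np.nan,
            "spatial_r2": r2 * f_sp if np.isfinite(f_sp) else np.nan,
        })
    table = pd.DataFrame(rows)
    table.attrs["sites"] = tuple(post.sites)
    return table
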