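"""Shared Gibbs-sampling primitives.

The probit community model and the Gaussian environment model use the
same latent-factor machinery: site-level factor scores with a spatially
structured Gaussian-process prior ``exp(-d / alpha)``, per-response
loadings with standard-normal priors, and a discrete grid posterior for
the spatial range ``alpha`` of each factor. Those updates, plus the
numerically safe truncated-normal sampler for the probit latent layer,
live here.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import ndtr, ndtri

__all__ = [
    "draw_truncated_probit",
    "exp_decay_kernel",
    "SpatialGrid",
    "draw_factor_scores",
    "draw_loadings",
    "draw_alpha_index",
    "draw_mvn_from_precision",
    "sample_log_weights",
]

_TINY = 1e-300
_MEAN_CLIP = 37.0  # beyond +-37 sd the normal cdf underflows double precision


def draw_truncated_probit(rng: np.random.Generator, mean: np.ndarray,
                          y: np.ndarray) -> np.ndarray:
    """Draw latent probit variables ``z ~ N(mean, 1)`` truncated by ``y``.

    Cells with ``y == 1`` are drawn from the positive half-line, cells
    with ``y == 0`` from the non-positive half-line, via the inverse-CDF
    method evaluated in the *smaller* tail so that extreme means remain
    finite and correctly signed.
    """
    mean = np.clip(np.asarray(mean, dtype=float), -_MEAN_CLIP, _MEAN_CLIP)
    u = rng.random(size=mean.shape)
    pos = np.asarray(y, dtype=bool)
    z = np.empty_like(mean)
    # z > 0: P(Z > z) = u * P(Z > 0); evaluated via the upper-tail quantile
    m = mean[pos]
    p_above = ndtr(m)
    z[pos] = m - ndtri(np.clip(u[pos] * p_above, _TINY, 1.0))
    # z <= 0 by reflection
    m = mean[~pos]
    p_below = ndtr(-m)
    z[~pos] = m + ndtri(np.clip(u[~pos] * p_below, _TINY, 1.0))
    return z


def exp_decay_kernel(coords: np.ndarray, alpha: float,
                     jitter: float = 1e-8) -> np.ndarray:
    """Exponential spatial covariance ``exp(-d / alpha)``; ``alpha == 0``
    degenerates to the identity (spatially unstructured effect)."""
    n = coords.shape[0]
    if alpha == 0:
        return np.eye(n)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    K = np.exp(-d / alpha)
    K[np.diag_indices(n)] += jitter
    return K


class SpatialGrid:
    """Precomputed inverse and log-determinant of the spatial kernel on a
    discrete grid of range parameters ``alpha``.

    The site set is fixed during a model fit, so each kernel is factored
    once; factor-score updates and the discrete ``alpha`` posterior then
    reuse the cached inverses.
    """

    def __init__(self, coords: np.ndarray, alphas: np.ndarray):
        self.coords = np.asarray(coords, dtype=float)
        self.alphas = np.asarray(alphas, dtype=float)
        self.inverses = []
        self.logdets = []
        for a in self.alphas:
            K = exp_decay_kernel(self.coords, a)
            c, low = cho_factor(K, lower=True)
            self.inverses.append(cho_solve((c, low), np.eye(K.shape[0])))
            self.logdets.append(2.0 * np.log(np.diag(c)).sum())

    @classmethod
    def from_landscape(cls, coords: np.ndarray, n_alphas: int) -> "SpatialGrid":
        """Grid from 0 (unstructured) to the landscape diagonal."""
        coords = np.asarray(coords, dtype=float)
        span = coords.max(axis=0) - coords.min(axis=0)
        diag = float(np.sqrt((span ** 2).sum()))
        if diag <= 0:
            diag = 1.0
        return cls(coords, np.linspace(0.0, diag, n_alphas))

    def __len__(self) -> int:
        return len(self.alphas)


def sample_log_weights(rng: np.random.Generator, log_w: np.ndarray) -> int:
    """Sample an index from unnormalised log weights."""
    log_w = np.asarray(log_w, dtype=float)
    finite = np.isfinite(log_w)
    if not finite.any():
        raise FloatingPointError("all grid log-weights are non-finite")
    w = np.where(finite, np.exp(log_w - log_w[finite].max()), 0.0)
    w /= w.sum()
    return int(rng.choice(len(w), p=w))


def draw_mvn_from_precision(rng: np.random.Generator, precision: np.ndarray,
                            rhs: np.ndarray) -> np.ndarray:
    """Draw from N(Q^{-1} rhs, Q^{-1}) given precision Q, via Cholesky."""
    if not np.all(np.isfinite(precision)):
        raise FloatingPointError("non-finite conditional precision")
    L = cholesky(precision, lower=True)
    mean = cho_solve((L, True), rhs)
    noise = solve_triangular(L.T, rng.standard_normal(rhs.shape[0]), lower=False)
    return mean + noise


def draw_factor_scores(rng: np.random.Generator, resid: np.ndarray,
                       loadings: np.ndarray, inv_noise_var: np.ndarray,
                       k_inverses) -> np.ndarray:
    """Update site-level factor scores ``eta`` (n_sites x n_factors).

    ``resid`` is the residual matrix (n_sites x n_responses) after removing
    the fixed effects, ``loadings`` is (n_factors x n_responses), and
    ``inv_noise_var`` the per-response residual precision (all ones for the
    probit layer). ``k_inverses`` holds one spatial-prior precision matrix
    per factor.
    """
    n, _ = resid.shape
    n_f = loadings.shape[0]
    A = (loadings * inv_noise_var[None, :]) @ loadings.T  # n_f x n_f
    Q = np.kron(A, np.eye(n))
    for h in range(n_f):
        sl = slice(h * n, (h + 1) * n)
        Q[sl, sl] += k_inverses[h]
    rhs = ((resid * inv_noise_var[None, :]) @ loadings.T).ravel(order="F")
    draw = draw_mvn_from_precision(rng, Q, rhs)
    return draw.reshape((n, n_f), order="F")


def draw_loadings(rng: np.random.Generator, resid: np.ndarray,
                  eta: np.ndarray, inv_noise_var: np.ndarray,
                  prior_var: float = 1.0) -> np.ndarray:
    """Update factor loadings (n_factors x n_responses), N(0, prior_var) prior."""
    n_f = eta.shape[1]
    ete = eta.T @ eta
    lam = np.empty((n_f, resid.shape[1]))
    uniq = np.unique(inv_noise_var)
    for v in uniq:
        cols = np.flatnonzero(inv_noise_var == v)
        Q = v * ete + np.eye(n_f) / prior_var
        L = cholesky(Q, lower=True)
        rhs = v * (eta.T @ resid[:, cols])
        mean = cho_solve((L, True), rhs)
        noise = solve_triangular(L.T, rng.standard_normal((n_f, cols.size)),
                                 lower=False)
        lam[:, cols] = mean + noise
    return lam


def draw_alpha_index(rng: np.random.Generator, eta_h: np.ndarray,
                     grid: SpatialGrid) -> int:
    """Discrete grid posterior for the spatial range of one factor."""
    log_w = np.empty(len(grid))
    for a in range(len(grid)):
        quad = eta_h @ grid.inverses[a] @ eta_h
        log_w[a] = -0.5 * grid.logdets[a] - 0.5 * quad
    return sample_log_weights(rng, log_w)
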