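"""Gaussian linear algebra for the CAR-within-clusters model.

The observation model is ``y_{i,t} ~ N(alpha_i + beta_i * x_t, sigma^2)``
with a standardized time covariate x (sum zero).  Within each cluster of
the intercept partition, ``alpha_k ~ CAR(alphabar_k, a1*sigma^2, W_k)``
using the Leroux conditional autoregression, whose joint covariance is
``tau^2 * Sigma_CAR`` with ``Sigma_CAR = [rho*W* + (1-rho)I]^{-1}`` (W* the
unweighted graph Laplacian of the cluster subgraph; 1/(1-rho) for a
singleton cluster).  Grand cluster means carry N(0, a2*sigma^2) priors and
``sigma^2 ~ IG(nu/2, nu*lambda/2)``; slopes are treated analogously with
(b1, b2).

Everything Gaussian integrates out analytically.  After marginalizing the
grand means, the covariance multiplier of cluster k is
``V_k = a1*Sigma_CAR + a2*11'``.  Because sum_t x_t = 0 the intercept and
slope designs are orthogonal, so the marginal likelihood p(y | gamma)
decomposes into independent per-cluster determinant and quadratic-form
terms — one set per intercept cluster (driven by the per-unit time sums of
y) and one per slope cluster (driven by sum_t x_t y_{i,t}) — plus a
residual sum of squares; integrating sigma^2 yields a multivariate-t log
density.  All per-cluster terms are computed from Cholesky factors of the
cluster precision ``rho*W* + (1-rho)I`` (plus a diagonal shift) and
rank-one identities for the grand-mean term, and are cached so that local
moves that change one cluster only recompute the affected terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.special import gammaln

from .areal_data import ArealTimeSeries
from .partition_prior import SpatialPartition, log_ep_prior

__all__ = [
    "ModelHyperparams",
    "car_covariance",
    "CarMarginal",
    "log_marginal_likelihood",
    "log_joint",
    "conditional_posterior_means",
    "predict",
]


@dataclass(frozen=True)
class ModelHyperparams:
    """Hyperparameters of the CAR-within-clusters model.

    rho: within-cluster spatial autocorrelation in [0, 1).
    a1, a2: CAR scale and grand-mean variance multipliers for intercepts.
    b1, b2: the same for slopes.
    nu_sigma, lambda_sigma: the residual variance prior is
        IG(nu_sigma/2, nu_sigma*lambda_sigma/2) (shape/rate), so
        lambda_sigma is a prior guess of sigma^2.
    eta: concentration of the Ewens-Pitman partition prior.
    """

    a1: float
    a2: float
    b1: float
    b2: float
    nu_sigma: float
    lambda_sigma: float
    rho: float = 0.9
    eta: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        for name in ("a1", "a2", "b1", "b2", "nu_sigma", "lambda_sigma", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **kw) -> "ModelHyperparams":
        return replace(self, **kw)


def _subgraph_precision(W_sub: np.ndarray, rho: float) -> np.ndarray:
    """Leroux precision rho*W* + (1-rho)I of a cluster subgraph."""
    n = W_sub.shape[0]
    deg = W_sub.sum(axis=1)
    return rho * (np.diag(deg.astype(float)) - W_sub) + (1.0 - rho) * np.eye(n)


def _chol(mat: np.ndarray):
    """Cholesky factor with a single 1e-10 jitter retry on failure."""
    try:
        return cho_factor(mat, lower=True)
    except LinAlgError:
        return cho_factor(mat + 1e-10 * np.eye(mat.shape[0]), lower=True)


def car_covariance(subgraph_W, rho: float) -> np.ndarray:
    """Exact CAR covariance ``[rho*W* + (1-rho)I]^{-1}`` of a connected
    cluster subgraph (``[[1/(1-rho)]]`` for a single unit)."""
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    W_sub = np.asarray(subgraph_W, dtype=float)
    n = W_sub.shape[0]
    if n == 1:
        return np.array([[1.0 / (1.0 - rho)]])
    P = _subgraph_precision(W_sub, rho)
    c = _chol(P)
    return cho_solve(c, np.eye(n))


class CarMarginal:
    """Marginal-likelihood engine for a fixed dataset, graph, and
    hyperparameters, with per-cluster caching for incremental updates.

    Every per-cluster contribution depends only on the cluster member set,
    so a local move that alters one or two clusters of one partition
    reuses the cached terms of all untouched clusters.
    """

    def __init__(self, data: ArealTimeSeries, hp: ModelHyperparams, graph=None):
        graph = graph if graph is not None else data.graph
        if graph is None:
            raise ValueError("an adjacency graph is required")
        if graph.n_units != data.n_units:
            raise ValueError("graph size does not match data")
        self.data = data
        self.graph = graph
        self.hp = hp
        y, x = data.y, data.x
        self.s_alpha = y.sum(axis=1)  # per-unit time sums
        self.s_beta = y @ x  # per-unit sum_t x_t y_{i,t}
        self.yty = float((y**2).sum())
        self.d_alpha = float(data.n_times)  # intercept design norm (T)
        self.d_beta = float(x @ x)  # slope design norm (sum x^2 = T-1)
        self.NT = data.n_units * data.n_times
        self._prec_cache: dict = {}
        self._term_cache: dict = {"alpha": {}, "beta": {}}
        nu, lam = hp.nu_sigma, hp.lambda_sigma
        self._const = (
            -0.5 * self.NT * np.log(2.0 * np.pi)
            + 0.5 * nu * np.log(0.5 * nu * lam)
            - gammaln(0.5 * nu)
            + gammaln(0.5 * (nu + self.NT))
        )

    # -- per-cluster primitives ------------------------------------------

    def _precision_factors(self, units: tuple):
        """Cholesky factors of P and P + d*a I for both design norms."""
        cached = self._prec_cache.get(units)
        if cached is None:
            idx = np.asarray(units)
            W_sub = self.graph.W[np.ix_(idx, idx)].astype(float)
            P = _subgraph_precision(W_sub, self.hp.rho)
            cP = _chol(P)
            logdetP = 2.0 * np.log(np.diag(cP[0])).sum()
            cached = (P, cP, logdetP)
            self._prec_cache[units] = cached
        return cached

    def _cluster_terms(self, which: str, units: tuple):
        """(log-determinant, quadratic-form, posterior-mean) contributions
        of one cluster.

        With P the cluster precision, B = (P + d*a1*I)/a1 and kappa the
        rank-one grand-mean correction, the cluster contributes
        ``logdet(I + d V_k)`` to the overall log determinant and
        ``s' (V_k^{-1} + dI)^{-1} s`` to the explained quadratic form,
        where ``V_k = a1 P^{-1} + a2 11'``.  The conditional posterior mean
        of the cluster's parameters is ``(V_k^{-1} + dI)^{-1} s`` (free of
        sigma^2 since all covariances scale with it).
        """
        cached = self._term_cache[which].get(units)
        if cached is not None:
            return cached
        hp = self.hp
        if which == "alpha":
            d, a1, a2, s_full = self.d_alpha, hp.a1, hp.a2, self.s_alpha
        else:
            d, a1, a2, s_full = self.d_beta, hp.b1, hp.b2, self.s_beta
        idx = np.asarray(units)
        n = idx.size
        s = s_full[idx]
        one_minus_rho = 1.0 - hp.rho
        P, _, logdetP = self._precision_factors(units)
        G = P + (d * a1) * np.eye(n)
        cG = _chol(G)
        logdetG = 2.0 * np.log(np.diag(cG[0])).sum()
        rhs = np.column_stack([np.ones(n), s])
        sol = cho_solve(cG, rhs)
        u, w = sol[:, 0], sol[:, 1]  # G^{-1}1, G^{-1}s
        t1 = float(np.ones(n) @ u)
        ow = float(np.ones(n) @ w)
        sw = float(s @ w)
        r = a2 / a1
        denom0 = 1.0 + r * one_minus_rho * n
        kappa = (a2 / a1**2) * one_minus_rho**2 / denom0
        denom = 1.0 - kappa * a1 * t1
        logdet = logdetG - logdetP + np.log(denom0) + np.log(denom)
        quad = a1 * sw + kappa * (a1 * ow) ** 2 / denom
        mean = a1 * w + (kappa * a1 * ow / denom) * (a1 * u)
        cached = (float(logdet), float(quad), mean)
        self._term_cache[which][units] = cached
        return cached

    @staticmethod
    def _cluster_keys(partition: SpatialPartition):
        return [tuple(int(i) for i in c) for c in partition.clusters()]

    # -- particle-level quantities ---------------------------------------

    def log_marginal(self, particle) -> float:
        """Exact log marginal likelihood log p(y | gamma)."""
        nu, lam = self.hp.nu_sigma, self.hp.lambda_sigma
        logdet = 0.0
        quad = 0.0
        for which, partition in (("alpha", particle.gamma_alpha), ("beta", particle.gamma_beta)):
            for key in self._cluster_keys(partition):
                ld, q, _ = self._cluster_terms(which, key)
                logdet += ld
                quad += q
        Q = self.yty - quad
        return float(
            self._const - 0.5 * logdet - 0.5 * (nu + self.NT) * np.log(0.5 * (nu * lam + Q))
        )

    def log_joint(self, particle) -> float:
        """Unnormalized log p(y, gamma): marginal likelihood plus the
        Ewens-Pitman log prior of both partitions (the spatial-truncation
        normalizer is a shared constant and omitted)."""
        return (
            self.log_marginal(particle)
            + log_ep_prior(particle.gamma_alpha, self.hp.eta)
            + log_ep_prior(particle.gamma_beta, self.hp.eta)
        )

    def conditional_means(self, particle):
        """Conditional posterior means given the particle.

        Returns (alpha_hat, beta_hat, alphabar_hat, betabar_hat): unit-level
        intercept/slope means and grand cluster means.
        """
        hp = self.hp
        out = {}
        for which, partition, a1, a2 in (
            ("alpha", particle.gamma_alpha, hp.a1, hp.a2),
            ("beta", particle.gamma_beta, hp.b1, hp.b2),
        ):
            unit_means = np.empty(self.data.n_units)
            bar = np.empty(partition.n_clusters)
            for k, key in enumerate(self._cluster_keys(partition)):
                _, _, mean = self._cluster_terms(which, key)
                idx = np.asarray(key)
                unit_means[idx] = mean
                # E[grand mean | theta] = (1-rho) sum(theta) / ((1-rho)n + a1/a2)
                omr = 1.0 - hp.rho
                bar[k] = omr * mean.sum() / (omr * idx.size + a1 / a2)
            out[which] = (unit_means, bar)
        return out["alpha"][0], out["beta"][0], out["alpha"][1], out["beta"][1]


# ---------------------------------------------------------------------------
# module-level wrappers (build a throwaway engine; optimization code uses a
# shared CarMarginal directly to benefit from the cluster-term cache)


def log_marginal_likelihood(data, particle, hp, graph=None) -> float:
    return CarMarginal(data, hp, graph).log_marginal(particle)


def log_joint(data, particle, hp, graph=None) -> float:
    return CarMarginal(data, hp, graph).log_joint(particle)


def conditional_posterior_means(data, particle, hp, graph=None):
    return CarMarginal(data, hp, graph).conditional_means(particle)


def predict(data, particle_set, x_new: float, hp=None, graph=None,
            weights: str = "untempered") -> np.ndarray:
    """Model-averaged forecast ``E[alpha_i + beta_i * x_new | y]``.

    Averages conditional means over the particle set under the truncated
    posterior weights (untempered by default; duplicate particles count
    once).  ``hp`` defaults to the hyperparameters the particle set was fit
    with, if recorded.
    """
    if len(particle_set.particles) == 0:
        raise ValueError("empty particle set")
    hp = hp if hp is not None else particle_set.hp
    if hp is None:
        raise ValueError("hyperparameters required for prediction")
    engine = CarMarginal(data, hp, graph)
    keys, wts = particle_set.distinct_weights(kind=weights)
    forecast = np.zeros(data.n_units)
    for key, wt in zip(keys, wts):
        particle = particle_set.particles[key]
        alpha_hat, beta_hat, _, _ = engine.conditional_means(particle)
        forecast += wt * (alpha_hat + beta_hat * x_new)
    return forecast
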