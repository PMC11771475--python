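"""Independent oracles used by the test suite.

These deliberately avoid the package's per-cluster decompositions: the
marginal likelihood oracle builds the full NT x NT covariance and calls the
multivariate-t density, and the quadrature oracle integrates the Gaussian
likelihood against the inverse-gamma prior numerically.
"""

import numpy as np
from scipy import integrate, stats

import carclust as cc


def dense_v(data, partition, s1, s2, rho):
    """Dense N x N prior covariance multiplier with per-cluster blocks
    s1 * Sigma_CAR + s2 * 11'."""
    n = data.n_units
    V = np.zeros((n, n))
    for members in partition.clusters():
        W_sub = data.graph.W[np.ix_(members, members)].astype(float)
        V[np.ix_(members, members)] = s1 * cc.car_covariance(W_sub, rho) + s2
    return V


def dense_scale_matrix(data, particle, hp):
    """Full NT x NT scale matrix I + Da Va Da' + Db Vb Db' (row-major y)."""
    n, T = data.y.shape
    Da = np.zeros((n * T, n))
    Db = np.zeros((n * T, n))
    for i in range(n):
        Da[i * T : (i + 1) * T, i] = 1.0
        Db[i * T : (i + 1) * T, i] = data.x
    Va = dense_v(data, particle.gamma_alpha, hp.a1, hp.a2, hp.rho)
    Vb = dense_v(data, particle.gamma_beta, hp.b1, hp.b2, hp.rho)
    return np.eye(n * T) + Da @ Va @ Da.T + Db @ Vb @ Db.T


def log_marginal_dense(data, particle, hp):
    """Marginal likelihood via the multivariate-t density on the full
    observation vector."""
    M = dense_scale_matrix(data, particle, hp)
    return float(
        stats.multivariate_t(
            loc=np.zeros(M.shape[0]), shape=hp.lambda_sigma * M, df=hp.nu_sigma
        ).logpdf(data.y.reshape(-1))
    )


def log_marginal_quadrature(data, particle, hp):
    """Marginal likelihood by 1-D quadrature over sigma^2."""
    M = dense_scale_matrix(data, particle, hp)
    yv = data.y.reshape(-1)
    nu, lam = hp.nu_sigma, hp.lambda_sigma
    ig = stats.invgamma(a=nu / 2.0, scale=nu * lam / 2.0)
    sign, logdet = np.linalg.slogdet(M)
    assert sign > 0
    quad = yv @ np.linalg.solve(M, yv)
    nt = len(yv)

    peak = (quad + nu * lam) / (nt + nu + 2.0)  # mode of the integrand

    def log_f(s2):
        return (
            -0.5 * nt * np.log(2 * np.pi * s2)
            - 0.5 * logdet
            - 0.5 * quad / s2
            + ig.logpdf(s2)
        )

    shift = log_f(peak)
    # integrate in u = log(sigma^2): f(e^u) e^u du, centred on the mode
    u0 = np.log(peak)
    val, _ = integrate.quad(
        lambda u: np.exp(log_f(np.exp(u)) - shift + u), u0 - 25, u0 + 25, limit=400
    )
    return float(np.log(val) + shift)


def enumerate_particles(graph):
    parts = cc.enumerate_spatial_partitions(graph)
    return [cc.Particle(pa, pb) for pa in parts for pb in parts]


def exact_top_particles(data, hp, L):
    """Exhaustive ranking of all particles by log joint posterior."""
    eng = cc.CarMarginal(data, hp)
    scored = [(eng.log_joint(p), p) for p in enumerate_particles(data.graph)]
    scored.sort(key=lambda t: -t[0])
    return scored[:L], scored


def path_instance(seed):
    """Canonical strongly separated instance on the 1x4 path: two intercept
    clusters with means -2/+2 and two slope clusters (sizes 1 and 3) with
    means -2/+2, unit noise variance, T=12."""
    g = cc.make_grid(1, 4)
    ga = cc.SpatialPartition([0, 0, 1, 1])
    gb = cc.SpatialPartition([0, 1, 1, 1])
    data, truth = cc.simulate_partitioned(
        g, ga, gb, alpha_bar=[-2.0, 2.0], beta_bar=[-2.0, 2.0],
        sigma2=1.0, T=12, seed=seed,
    )
    hp = cc.ModelHyperparams(
        a1=0.01, a2=4.0, b1=0.01, b2=2.0, nu_sigma=10.0, lambda_sigma=1.0
    )
    return data, truth, hp
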