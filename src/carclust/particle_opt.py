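"""Entropy-penalized ensemble search for high-posterior partition pairs.

The discrete posterior over particles (pairs of spatial partitions, one for
intercepts and one for slopes) is approximated by a distribution supported
on L particles with importance weights w.  The L best particles solve

    max_{Gamma, w}  sum_l w_l log p(y, gamma_l) + lambda * H(Gamma, w)

whose optimum, for any penalty lambda > 0, consists of the L particles of
largest posterior mass with weights proportional to the tempered posterior
``p(gamma_l | y)^{1/lambda}``.  Entropy is computed over *distinct*
particles (duplicates merged), so the penalty actively discourages
different greedy search paths from collapsing onto the same point.

The optimizer is coordinate ascent: sweep over particles, greedily updating
each constituent partition over a pooled candidate set of island / border /
merge / split / split-and-merge moves, then refresh the weights in closed
form.  Convergence is declared when a full sweep improves the objective by
less than ``rel_tol`` *and* no single-unit island move on any particle
improves it (a local-convergence certificate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .areal_data import ArealTimeSeries
from .car_model import CarMarginal, ModelHyperparams
from .partition_prior import SpatialPartition
from .partition_moves import (
    all_island_sweep,
    border_moves,
    connected_components,
    island_moves,
    merge_moves,
    split_merge_moves,
    split_moves,
)

__all__ = [
    "Particle",
    "ParticleSet",
    "SearchConfig",
    "entropy",
    "optimal_weights",
    "objective",
    "greedy_partition_update",
    "particle_optimize",
    "compute_mle",
    "initialize_particles",
    "fit_hyperparameters",
]


@dataclass(frozen=True)
class Particle:
    """A pair of spatial partitions: intercepts and slopes."""

    gamma_alpha: SpatialPartition
    gamma_beta: SpatialPartition

    @property
    def key(self):
        return (self.gamma_alpha.assignment, self.gamma_beta.assignment)

    def with_partition(self, which: str, partition: SpatialPartition) -> "Particle":
        if which == "alpha":
            return Particle(partition, self.gamma_beta)
        return Particle(self.gamma_alpha, partition)


@dataclass
class SearchConfig:
    """Knobs of the particle optimizer.

    ``lam`` is the entropy penalty (inverse temperature); the global optimum
    is lambda-free but the local search is not, and values of 10-100 keep
    the particles spread over distinct modes.
    """

    L: int = 10
    lam: float = 100.0
    seed: int = 0
    max_sweeps: int = 100
    rel_tol: float = 1e-8
    split_cap: int = 5
    island_quantile: float = 0.05

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be at least 1")
        if self.lam <= 0:
            raise ValueError("lam must be positive")


@dataclass
class ParticleSet:
    """L particles with tempered weights and cached log joint posteriors."""

    particles: list
    weights: np.ndarray
    log_joints: np.ndarray
    lam: float = 1.0
    hp: ModelHyperparams | None = None
    converged: bool = True
    n_sweeps: int = 0
    objective_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.log_joints = np.asarray(self.log_joints, dtype=float)
        L = len(self.particles)
        if self.weights.shape != (L,) or self.log_joints.shape != (L,):
            raise ValueError("weights/log_joints must match the number of particles")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must lie on the simplex")

    def distinct_weights(self, kind: str = "untempered"):
        """Indices of one representative per distinct particle and their
        merged truncated-posterior weights (duplicates counted once).

        ``kind='untempered'`` uses softmax(log_joints); ``'tempered'`` uses
        softmax(log_joints / lam); ``'current'`` merges the stored weights.
        """
        reps: dict = {}
        for i, p in enumerate(self.particles):
            reps.setdefault(p.key, i)
        idx = np.array(sorted(reps.values()))
        if kind == "current":
            merged: dict = {}
            for i, p in enumerate(self.particles):
                merged[p.key] = merged.get(p.key, 0.0) + self.weights[i]
            w = np.array([merged[self.particles[i].key] for i in idx])
        else:
            lj = self.log_joints[idx]
            if kind == "tempered":
                lj = lj / self.lam
            w = np.exp(lj - logsumexp(lj))
        return idx, w

    def to_dict(self) -> dict:
        idx, untempered = self.distinct_weights("untempered")
        untemp_full = np.zeros(len(self.particles))
        untemp_full[idx] = untempered
        return {
            "particles": [
                {
                    "gamma_alpha": list(p.gamma_alpha.assignment),
                    "gamma_beta": list(p.gamma_beta.assignment),
                }
                for p in self.particles
            ],
            "weights_tempered": self.weights.tolist(),
            "weights_untempered": untemp_full.tolist(),
            "log_joints": self.log_joints.tolist(),
            "lam": self.lam,
            "converged": self.converged,
            "n_sweeps": self.n_sweeps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParticleSet":
        particles = [
            Particle(SpatialPartition(p["gamma_alpha"]), SpatialPartition(p["gamma_beta"]))
            for p in d["particles"]
        ]
        return cls(
            particles=particles,
            weights=np.array(d["weights_tempered"]),
            log_joints=np.array(d["log_joints"]),
            lam=d.get("lam", 1.0),
            converged=d.get("converged", True),
            n_sweeps=d.get("n_sweeps", 0),
        )


def _merged_weights(keys, weights) -> dict:
    merged: dict = {}
    for key, w in zip(keys, weights):
        merged[key] = merged.get(key, 0.0) + w
    return merged


def _entropy_of(merged: dict) -> float:
    p = np.array([w for w in merged.values() if w > 0.0])
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def entropy(particle_set: ParticleSet) -> float:
    """Entropy of the approximating distribution over *distinct* particles
    (duplicates merged by summing their weights)."""
    keys = [p.key for p in particle_set.particles]
    return _entropy_of(_merged_weights(keys, particle_set.weights))


def optimal_weights(log_joints, particles, lam: float) -> np.ndarray:
    """Closed-form optimal weights: softmax of log_joints / lam over
    distinct particles, with each merged weight shared equally among its
    duplicates."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    log_joints = np.asarray(log_joints, dtype=float)
    keys = [p.key for p in particles]
    groups: dict = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    reps = list(groups)
    lj = np.array([log_joints[groups[key][0]] for key in reps]) / lam
    merged = np.exp(lj - logsumexp(lj))
    w = np.empty(len(keys))
    for key, wk in zip(reps, merged):
        members = groups[key]
        w[members] = wk / len(members)
    return w


def objective(particle_set: ParticleSet, lam: float | None = None) -> float:
    """Ensemble objective: weighted log joint posterior plus lam * entropy."""
    lam = particle_set.lam if lam is None else lam
    return float(
        particle_set.weights @ particle_set.log_joints + lam * entropy(particle_set)
    )


def _candidate_pool(partition, graph, estimates, grand_means, config):
    cands = []
    cands += island_moves(partition, graph, estimates, config.island_quantile)
    cands += border_moves(partition, graph)
    if partition.n_clusters >= 2:
        cands += merge_moves(partition, graph, grand_means)
    cands += split_moves(partition, graph, estimates, config.split_cap)
    if partition.n_clusters >= 2:
        cands += split_merge_moves(partition, graph, estimates, grand_means, config.split_cap)
    seen, out = {partition.assignment}, []
    for c in cands:
        if c.partition.assignment not in seen:
            seen.add(c.partition.assignment)
            out.append(c.partition)
    return out


def _best_update(particle_set, l, which, engine, config, candidates=None):
    """Evaluate the full objective at each candidate partition for particle
    ``l`` and return (particle, log_joint, improvement) for the best strict
    improvement, or (current, current_lj, 0.0)."""
    lam = config.lam
    particle = particle_set.particles[l]
    graph = engine.graph
    if candidates is None:
        alpha_hat, beta_hat, abar, bbar = engine.conditional_means(particle)
        est, gm = (alpha_hat, abar) if which == "alpha" else (beta_hat, bbar)
        partition = getattr(particle, f"gamma_{which}")
        candidates = _candidate_pool(partition, graph, est, gm, config)
    w = particle_set.weights
    keys = [p.key for p in particle_set.particles]
    merged_others = _merged_weights(
        [k for i, k in enumerate(keys) if i != l],
        [w[i] for i in range(len(keys)) if i != l],
    )
    def obj_with(key, lj):
        merged = dict(merged_others)
        merged[key] = merged.get(key, 0.0) + w[l]
        return w @ particle_set.log_joints + w[l] * (lj - particle_set.log_joints[l]) + lam * _entropy_of(merged)

    cur_obj = obj_with(particle.key, particle_set.log_joints[l])
    best = (particle, float(particle_set.log_joints[l]), cur_obj, None)
    for cand in candidates:
        new_particle = particle.with_partition(which, cand)
        lj = engine.log_joint(new_particle)
        val = obj_with(new_particle.key, lj)
        if val > best[2] + 1e-12:
            best = (new_particle, lj, val, cand)
        elif best[3] is not None and abs(val - best[2]) <= 1e-12:
            # tie-break: fewer clusters, then lexicographically smaller form
            old_k = getattr(best[0], f"gamma_{which}").n_clusters
            if (cand.n_clusters, cand.assignment) < (old_k, getattr(best[0], f"gamma_{which}").assignment):
                best = (new_particle, lj, val, cand)
    improvement = best[2] - cur_obj
    return best[0], best[1], improvement


def greedy_partition_update(particle, which, data, hp, particle_set, lam,
                            config=None, engine=None):
    """Single greedy move on one constituent partition of one particle,
    scored by the full entropy-penalized objective (so coexisting particles
    repel duplicates).  Returns the improved particle, or the input
    unchanged if no candidate strictly improves the objective."""
    config = config or SearchConfig(L=len(particle_set.particles), lam=lam)
    config.lam = lam
    engine = engine or CarMarginal(data, hp)
    l = next(
        i for i, p in enumerate(particle_set.particles) if p.key == particle.key
    )
    new_particle, _, improvement = _best_update(particle_set, l, which, engine, config)
    return new_particle if improvement > 0 else particle


def particle_optimize(data, hp, config: SearchConfig, graph=None, init=None) -> ParticleSet:
    """Coordinate-ascent search for the L highest-posterior particles.

    Returns a ParticleSet sorted by log joint posterior (descending) whose
    ``weights`` are the tempered optimization weights; untempered truncated
    posterior weights are available via ``distinct_weights``.
    """
    engine = CarMarginal(data, hp, graph)
    if init is None:
        init = initialize_particles(data, hp, config, graph=graph, engine=engine)
    particles = list(init.particles)
    log_joints = np.asarray(init.log_joints, dtype=float).copy()
    lam = config.lam
    ps = ParticleSet(
        particles=particles,
        weights=optimal_weights(log_joints, particles, lam),
        log_joints=log_joints,
        lam=lam,
        hp=hp,
    )
    trace = [objective(ps)]
    converged = False
    sweeps = 0
    prev_obj = trace[0]
    while sweeps < config.max_sweeps:
        sweeps += 1
        for l in range(len(particles)):
            for which in ("alpha", "beta"):
                new_particle, lj, improvement = _best_update(ps, l, which, engine, config)
                if improvement > 0:
                    ps.particles[l] = new_particle
                    ps.log_joints[l] = lj
                    trace.append(objective(ps))
        ps.weights = optimal_weights(ps.log_joints, ps.particles, lam)
        obj = objective(ps)
        trace.append(obj)
        rel_impr = (obj - prev_obj) / max(abs(prev_obj), 1e-12)
        prev_obj = obj
        if rel_impr < config.rel_tol:
            # local-convergence certificate: no single-unit island move helps
            cert_improved = False
            for l in range(len(particles)):
                for which in ("alpha", "beta"):
                    partition = getattr(ps.particles[l], f"gamma_{which}")
                    cands = [c.partition for c in all_island_sweep(partition, engine.graph)]
                    if not cands:
                        continue
                    new_particle, lj, improvement = _best_update(
                        ps, l, which, engine, config, candidates=cands
                    )
                    if improvement > 0:
                        ps.particles[l] = new_particle
                        ps.log_joints[l] = lj
                        trace.append(objective(ps))
                        cert_improved = True
            if cert_improved:
                ps.weights = optimal_weights(ps.log_joints, ps.particles, lam)
                trace.append(objective(ps))
                prev_obj = trace[-1]
            else:
                converged = True
                break
    if not converged:
        warnings.warn("particle optimizer hit max_sweeps before converging")
    order = np.argsort(-ps.log_joints, kind="stable")
    ps.particles = [ps.particles[i] for i in order]
    ps.log_joints = ps.log_joints[order]
    ps.weights = optimal_weights(ps.log_joints, ps.particles, lam)
    ps.converged = converged
    ps.n_sweeps = sweeps
    ps.objective_trace = trace
    return ps


def compute_mle(data: ArealTimeSeries):
    """Per-unit least squares: intercepts (time means, since x is centered),
    slopes, and residual variances with denominator T-2."""
    T = data.n_times
    if T < 3:
        raise ValueError("need T >= 3 for residual degrees of freedom")
    x = data.x
    alpha = data.y.mean(axis=1)
    beta = (data.y @ x) / (x @ x)
    resid = data.y - alpha[:, None] - beta[:, None] * x[None, :]
    s2 = (resid**2).sum(axis=1) / (T - 2)
    return alpha, beta, s2


def _kmeans_partition(values: np.ndarray, K: int, graph, seed: int) -> SpatialPartition:
    """K-means clustering of a 1-D estimate vector, split into connected
    components so the result is a spatial partition."""
    if K == 1:
        labels = np.zeros(len(values), dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        labels = km.fit_predict(values.reshape(-1, 1))
    out = np.empty(len(values), dtype=int)
    nxt = 0
    for k in range(labels.max() + 1):
        members = np.flatnonzero(labels == k)
        if members.size == 0:
            continue
        for comp in connected_components(members, graph):
            out[comp] = nxt
            nxt += 1
    return SpatialPartition(out)


def initialize_particles(data, hp, config: SearchConfig, graph=None, engine=None) -> ParticleSet:
    """Seeded initialization from k-means on the per-unit least-squares
    estimates.

    Builds candidate partitions with K = 1..floor(eta*log N) clusters for
    each of the intercept and slope estimates, forms the (K, K') grid of
    particles, and samples L of them with replacement with probability
    proportional to their (untempered) joint posterior mass.
    """
    engine = engine or CarMarginal(data, hp, graph)
    graph = engine.graph
    alpha_mle, beta_mle, _ = compute_mle(data)
    N = data.n_units
    Kmax = max(1, int(np.round(hp.eta * np.log(N))))
    alpha_parts = [_kmeans_partition(alpha_mle, K, graph, config.seed) for K in range(1, Kmax + 1)]
    beta_parts = [_kmeans_partition(beta_mle, K, graph, config.seed) for K in range(1, Kmax + 1)]
    grid = [Particle(pa, pb) for pa in alpha_parts for pb in beta_parts]
    lj = np.array([engine.log_joint(p) for p in grid])
    probs = np.exp(lj - logsumexp(lj))
    rng = np.random.default_rng(config.seed)
    picks = rng.choice(len(grid), size=config.L, replace=True, p=probs)
    particles = [grid[i] for i in picks]
    log_joints = lj[picks]
    return ParticleSet(
        particles=particles,
        weights=optimal_weights(log_joints, particles, config.lam),
        log_joints=log_joints,
        lam=config.lam,
        hp=hp,
    )


def _ig_moment_match(m: float, v: float) -> tuple[float, float]:
    """(nu, lambda) of IG(nu/2, nu*lambda/2) with mean m and variance v.

    Closed form: nu = 2(2 + m^2/v), lambda = m(nu-2)/nu.  A degenerate
    sample variance falls back to nu=6 with lambda chosen to preserve the
    prior mean m.
    """
    if v <= 0 or not np.isfinite(v):
        return 6.0, 2.0 * m / 3.0
    nu = 2.0 * (2.0 + m * m / v)
    return nu, m * (nu - 2.0) / nu


def fit_hyperparameters(data, graph=None, seed: int = 0, rho: float = 0.9,
                        eta: float = 1.0, map_sweeps: int = 25) -> ModelHyperparams:
    """Data-dependent hyperparameters.

    The residual-variance prior IG(nu/2, nu*lambda/2) is moment-matched to
    the empirical distribution of the per-unit residual variances; the CAR
    scale multipliers start from the spread of the least-squares estimates
    and are refined by empirical Bayes — maximizing the marginal likelihood
    at a MAP particle over a coordinate-wise log-spaced grid (5 points per
    parameter spanning 1e-2 to 1e2 times the initial values, two passes).
    """
    graph = graph if graph is not None else data.graph
    alpha_mle, beta_mle, s2 = compute_mle(data)
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1)) if len(s2) > 1 else 0.0
    nu, lam_sig = _ig_moment_match(m, v)
    # Temporary CAR scales from the MLEs and the expected cluster count: a
    # k-means partition at K ~ eta*log N separates the spread of the MLEs
    # into a between-cluster part (-> a2, b2) and a within-cluster part,
    # from which the least-squares sampling noise is subtracted (-> a1, b1).
    K0 = max(2, int(np.round(eta * np.log(data.n_units))))
    K0 = min(K0, data.n_units)

    def _scales(mle, noise_var):
        part = _kmeans_partition(mle, K0, graph, seed)
        within, means = [], []
        for members in part.clusters():
            means.append(mle[members].mean())
            if members.size >= 2:
                within.append(np.var(mle[members], ddof=1))
        w = float(np.mean(within)) if within else noise_var
        between = float(np.var(means, ddof=1)) if len(means) >= 2 else w
        s1 = max((w - noise_var) / m, 1e-3)
        s2_ = max(between / m, 1e-3)
        return s1, s2_

    a1_0, a2_0 = _scales(alpha_mle, m / data.n_times)
    b1_0, b2_0 = _scales(beta_mle, m / float(data.x @ data.x))
    hp = ModelHyperparams(
        a1=a1_0, a2=a2_0, b1=b1_0, b2=b2_0,
        nu_sigma=nu, lambda_sigma=lam_sig, rho=rho, eta=eta,
    )
    cfg = SearchConfig(L=1, lam=1.0, seed=seed, max_sweeps=map_sweeps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = particle_optimize(data, hp, cfg, graph=graph)
    map_particle = ps.particles[0]
    init = {"a1": hp.a1, "a2": hp.a2, "b1": hp.b1, "b2": hp.b2}
    grids = {k: val * np.logspace(-2, 2, 5) for k, val in init.items()}
    best_val = CarMarginal(data, hp, graph).log_marginal(map_particle)
    for _ in range(2):
        for name, grid in grids.items():
            for g in grid:
                trial = hp.replace(**{name: float(g)})
                val = CarMarginal(data, trial, graph).log_marginal(map_particle)
                if val > best_val:
                    best_val, hp = val, trial
    return hp
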