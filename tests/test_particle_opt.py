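import warnings

import numpy as np
import pytest
from scipy.special import logsumexp

import carclust as cc
from carclust.car_model import CarMarginal
from carclust.particle_opt import _ig_moment_match

from helpers import exact_top_particles, path_instance
from conftest import random_spatial_partition


def toy_particles(n_distinct, n=4):
    """Distinct particles on a path (distinct slope partitions)."""
    out = []
    for k in range(n_distinct):
        labels = [0] * (n - k) + list(range(1, k + 1))
        out.append(
            cc.Particle(cc.SpatialPartition.single_cluster(n), cc.SpatialPartition(labels))
        )
    return out


class TestEntropy:
    def test_duplicates_merge_to_point_mass(self):
        p = toy_particles(1)[0]
        ps = cc.ParticleSet([p, p], [0.5, 0.5], [0.0, 0.0])
        assert cc.entropy(ps) == pytest.approx(0.0)

    def test_uniform_distinct_attains_log_l(self):
        parts = toy_particles(4)
        ps = cc.ParticleSet(parts, np.full(4, 0.25), np.zeros(4))
        assert cc.entropy(ps) == pytest.approx(np.log(4))

    def test_degenerate_weight_vector(self):
        parts = toy_particles(2)
        ps = cc.ParticleSet(parts, [1.0, 0.0], [0.0, 0.0])
        assert cc.entropy(ps) == 0.0


class TestOptimalWeights:
    def test_equal_log_joints_give_uniform(self):
        parts = toy_particles(3)
        w = cc.optimal_weights([-5.0, -5.0, -5.0], parts, lam=7.0)
        assert np.allclose(w, 1 / 3)

    def test_tempered_exponential_ratio(self):
        parts = toy_particles(2)
        lam = 6.5
        w = cc.optimal_weights([0.0, lam * np.log(2.0)], parts, lam=lam)
        assert np.allclose(w, [1 / 3, 2 / 3], atol=1e-12)

    def test_infinite_temperature_limit_is_uniform(self):
        parts = toy_particles(3)
        w = cc.optimal_weights([0.0, -50.0, -500.0], parts, lam=1e9)
        assert np.allclose(w, 1 / 3, atol=1e-6)

    def test_duplicates_share_merged_weight(self):
        p1, p2 = toy_particles(2)
        w = cc.optimal_weights([0.0, 0.0, 0.0], [p1, p1, p2], lam=1.0)
        assert np.allclose(w, [0.25, 0.25, 0.5])

    @pytest.mark.parametrize("lam", [1.0, 10.0, 100.0])
    def test_softmax_identity_and_objective_identity(self, lam):
        # Kullback-Leibler optimum: w* = softmax(lj/lam); at w* the
        # objective equals lam * logsumexp(lj/lam) for distinct particles
        rng = np.random.default_rng(0)
        parts = toy_particles(4)
        lj = rng.normal(scale=10, size=4)
        w = cc.optimal_weights(lj, parts, lam)
        assert np.allclose(w, np.exp(lj / lam - logsumexp(lj / lam)), atol=1e-12)
        ps = cc.ParticleSet(parts, w, lj, lam=lam)
        assert cc.objective(ps) == pytest.approx(lam * logsumexp(lj / lam), abs=1e-9)

    def test_optimal_weights_maximize_objective(self):
        rng = np.random.default_rng(1)
        parts = toy_particles(4)
        lj = rng.normal(scale=5, size=4)
        lam = 3.0
        best = cc.objective(cc.ParticleSet(parts, cc.optimal_weights(lj, parts, lam), lj, lam=lam))
        for _ in range(50):
            w = rng.dirichlet(np.ones(4))
            assert best >= cc.objective(cc.ParticleSet(parts, w, lj, lam=lam)) - 1e-9


class TestObjective:
    def test_single_particle_is_log_joint(self):
        p = toy_particles(1)
        ps = cc.ParticleSet(p, [1.0], [-12.3], lam=5.0)
        assert cc.objective(ps) == pytest.approx(-12.3)


class TestGreedyUpdate:
    def test_two_cluster_signal_recovered_in_one_move(self):
        # strong split in the intercepts on a 1x3 path: greedy must move the
        # single-cluster partition to the exhaustive argmax candidate
        g = cc.make_grid(1, 3)
        data, _ = cc.simulate_partitioned(
            g, cc.SpatialPartition([0, 0, 1]), cc.SpatialPartition([0, 0, 0]),
            alpha_bar=[-3.0, 3.0], beta_bar=[0.0], sigma2=0.5, T=12, seed=0,
        )
        hp = cc.ModelHyperparams(a1=0.01, a2=4.0, b1=0.01, b2=1.0, nu_sigma=10.0, lambda_sigma=0.5)
        start = cc.Particle(
            cc.SpatialPartition.single_cluster(3), cc.SpatialPartition.single_cluster(3)
        )
        ps = cc.ParticleSet([start], [1.0], [cc.log_joint(data, start, hp)], lam=10.0, hp=hp)
        new = cc.greedy_partition_update(start, "alpha", data, hp, ps, lam=10.0)
        eng = CarMarginal(data, hp)
        best_alpha = max(
            cc.enumerate_spatial_partitions(g),
            key=lambda pa: eng.log_joint(cc.Particle(pa, start.gamma_beta)),
        )
        assert new.gamma_alpha == best_alpha
        assert new.gamma_alpha.assignment == (0, 0, 1)

    def test_fixed_point_returns_input(self):
        data, truth, hp = path_instance(0)
        top, _ = exact_top_particles(data, hp, 1)
        lj0, p0 = top[0]
        ps = cc.ParticleSet([p0], [1.0], [lj0], lam=10.0, hp=hp)
        assert cc.greedy_partition_update(p0, "alpha", data, hp, ps, lam=10.0) == p0

    def test_entropy_pushes_duplicates_apart(self):
        # two particles on the MAP: updating the second must move it off the
        # duplicate even at a small posterior cost
        data, truth, hp = path_instance(1)
        top, _ = exact_top_particles(data, hp, 1)
        lj0, p0 = top[0]
        ps = cc.ParticleSet([p0, p0], [0.5, 0.5], [lj0, lj0], lam=100.0, hp=hp)
        moved = cc.greedy_partition_update(p0, "beta", data, hp, ps, lam=100.0)
        assert moved != p0


class TestParticleOptimize:
    def test_exact_map_and_topset_on_enumerable_path(self):
        data, truth, hp = path_instance(3)
        cfg = cc.SearchConfig(L=5, lam=10.0, seed=3, max_sweeps=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = cc.particle_optimize(data, hp, cfg)
        top, scored = exact_top_particles(data, hp, 8)
        assert ps.particles[0].key == top[0][1].key
        top8 = {p.key for _, p in top}
        assert {p.key for p in ps.particles} <= top8

    def test_objective_trace_nondecreasing(self):
        data, truth, hp = path_instance(4)
        cfg = cc.SearchConfig(L=5, lam=10.0, seed=4, max_sweeps=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = cc.particle_optimize(data, hp, cfg)
        tr = np.array(ps.objective_trace)
        assert np.all(np.diff(tr) >= -1e-9)

    def test_determinism_under_fixed_seed(self):
        data, truth, hp = path_instance(5)
        cfg = cc.SearchConfig(L=4, lam=10.0, seed=11, max_sweeps=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cc.particle_optimize(data, hp, cfg)
            b = cc.particle_optimize(data, hp, cfg)
        assert [p.key for p in a.particles] == [p.key for p in b.particles]
        assert np.allclose(a.weights, b.weights)
        assert np.allclose(a.log_joints, b.log_joints)

    def test_weights_on_simplex_and_sorted_output(self):
        data, truth, hp = path_instance(6)
        cfg = cc.SearchConfig(L=5, lam=10.0, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = cc.particle_optimize(data, hp, cfg)
        assert ps.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(ps.log_joints) <= 1e-12)


class TestComputeMle:
    def test_exact_linear_data(self):
        x = cc.standardize_times(6)
        y = 2.0 + 3.0 * np.tile(x, (2, 1))
        data = cc.ArealTimeSeries(y=y, x=x, areas=np.ones(2))
        a, b, s2 = cc.compute_mle(data)
        assert np.allclose(a, 2.0) and np.allclose(b, 3.0)
        assert np.allclose(s2, 0.0, atol=1e-25)

    def test_matches_lstsq_oracle(self):
        rng = np.random.default_rng(0)
        x = cc.standardize_times(9)
        y = rng.normal(size=(5, 9))
        data = cc.ArealTimeSeries(y=y, x=x, areas=np.ones(5))
        a, b, s2 = cc.compute_mle(data)
        X = np.column_stack([np.ones(9), x])
        for i in range(5):
            coef, res, *_ = np.linalg.lstsq(X, y[i], rcond=None)
            assert a[i] == pytest.approx(coef[0], abs=1e-10)
            assert b[i] == pytest.approx(coef[1], abs=1e-10)
            assert s2[i] == pytest.approx(res[0] / 7.0, abs=1e-10)

    def test_shift_moves_intercept_only(self):
        rng = np.random.default_rng(1)
        x = cc.standardize_times(7)
        y = rng.normal(size=(3, 7))
        d1 = cc.ArealTimeSeries(y=y, x=x, areas=np.ones(3))
        d2 = cc.ArealTimeSeries(y=y + 4.0, x=x, areas=np.ones(3))
        a1, b1, _ = cc.compute_mle(d1)
        a2, b2, _ = cc.compute_mle(d2)
        assert np.allclose(a2, a1 + 4.0) and np.allclose(b2, b1)


class TestInitialization:
    def test_initial_particles_are_spatial_and_weighted(self):
        g = cc.make_grid(4, 4)
        rng = np.random.default_rng(0)
        data, truth = cc.simulate_partitioned(
            g,
            cc.SpatialPartition([0] * 8 + [1] * 8),
            cc.SpatialPartition([0] * 16),
            alpha_bar=[-1.0, 1.0], beta_bar=[0.0], T=8, seed=0,
        )
        hp = cc.ModelHyperparams(a1=0.1, a2=1.0, b1=0.1, b2=1.0, nu_sigma=6.0, lambda_sigma=1.0)
        cfg = cc.SearchConfig(L=6, lam=10.0, seed=0)
        ps = cc.initialize_particles(data, hp, cfg)
        assert len(ps.particles) == 6
        for p in ps.particles:
            assert p.gamma_alpha.is_spatial(g) and p.gamma_beta.is_spatial(g)
        assert ps.weights.sum() == pytest.approx(1.0)


class TestHyperparameters:
    def test_ig_moment_match_closed_form(self):
        # exact inversion of mean/variance of IG(nu/2, nu*lam/2)
        nu, lam = 9.0, 1.7
        mean = nu * lam / (nu - 2.0)
        var = mean**2 / (nu / 2.0 - 2.0)
        nu_hat, lam_hat = _ig_moment_match(mean, var)
        assert nu_hat == pytest.approx(nu, abs=1e-10)
        assert lam_hat == pytest.approx(lam, abs=1e-10)

    def test_constant_residual_variances_fall_back_to_prior_mean(self):
        nu_hat, lam_hat = _ig_moment_match(1.0, 0.0)
        assert nu_hat * lam_hat / (nu_hat - 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_ig_simulation_roundtrip(self):
        rng = np.random.default_rng(0)
        nu, lam = 12.0, 0.8
        draws = 1.0 / rng.gamma(nu / 2.0, 2.0 / (nu * lam), size=100_000)
        nu_hat, lam_hat = _ig_moment_match(float(draws.mean()), float(draws.var(ddof=1)))
        assert nu_hat == pytest.approx(nu, rel=0.10)
        assert lam_hat == pytest.approx(lam, rel=0.10)

    def test_fitted_hyperparameters_track_generating_scales(self):
        g = cc.make_grid(5, 5)
        data, truth = cc.simulate_partitioned(
            g,
            cc.SpatialPartition([0] * 10 + [1] * 15),
            cc.SpatialPartition([0] * 25),
            alpha_bar=[-2.0, 2.0], beta_bar=[0.0], sigma2=1.0, T=12, seed=2,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hp = cc.fit_hyperparameters(data, seed=2)
        assert 0.5 < hp.lambda_sigma * hp.nu_sigma / (hp.nu_sigma - 2.0) < 2.0
        assert hp.a1 < hp.a2  # within-cluster spread below between-cluster
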