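import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import carclust as cc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def path4():
    return cc.make_grid(1, 4)


@pytest.fixture
def grid33():
    return cc.make_grid(3, 3)


def random_spatial_partition(graph, rng, n_merges=None):
    """Random spatial partition: start from singletons, merge random
    adjacent cluster pairs."""
    labels = np.arange(graph.n_units)
    edges = graph.edges()
    if n_merges is None:
        n_merges = rng.integers(0, graph.n_units)
    for _ in range(n_merges):
        u, v = edges[rng.integers(len(edges))]
        lu, lv = labels[u], labels[v]
        if lu != lv:
            labels[labels == lv] = lu
    return cc.SpatialPartition(labels)


def random_instance(rng, max_n=9, max_t=6):
    """Random (data, particle, hp) triple on a small random grid."""
    rows = int(rng.integers(1, 4))
    cols = int(rng.integers(1, max(2, max_n // rows) + 1))
    graph = cc.make_grid(rows, cols)
    n = graph.n_units
    T = int(rng.integers(3, max_t + 1))
    x = cc.standardize_times(T)
    y = rng.normal(size=(n, T)) * rng.uniform(0.5, 2.0)
    data = cc.ArealTimeSeries(y=y, x=x, areas=np.ones(n), graph=graph)
    hp = cc.ModelHyperparams(
        a1=float(rng.uniform(0.05, 2.0)),
        a2=float(rng.uniform(0.1, 4.0)),
        b1=float(rng.uniform(0.05, 2.0)),
        b2=float(rng.uniform(0.1, 4.0)),
        nu_sigma=float(rng.uniform(3.0, 20.0)),
        lambda_sigma=float(rng.uniform(0.2, 3.0)),
        rho=0.9,
    )
    particle = cc.Particle(
        random_spatial_partition(graph, rng), random_spatial_partition(graph, rng)
    )
    return data, particle, hp
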