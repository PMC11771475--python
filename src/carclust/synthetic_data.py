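"""Synthetic areal panels with known latent partition structure.

The reference design is a 20 x 20 rook-adjacency grid (N = 400) with two
fixed spatial partitions: the intercept partition has 10 connected clusters
with size multiset {237, 50, 30, 25, 20, 15, 12, 6, 4, 1} but only five
distinct cluster means (two clusters per mean), and the slope partition has
four clusters of sizes 188, 100, 100 and 12.  Within each cluster the
unit-level parameters are drawn from a CAR distribution around the cluster
mean, and observations follow y_{i,t} = alpha_i + beta_i x_t + N(0, sigma^2)
over T = 12 standardized time points with unit areas.

Three separation settings (high / medium / low) shrink the gaps between
distinct cluster means so the cluster structure goes from visually obvious
to barely detectable.

Intercept partition layout (rows x columns of the 20 x 20 grid; cluster
letters, sizes in parentheses)::

    rows 0-4   cols 0-9  -> B (50)     rows 0-2  cols 10-19 -> C (30)
    rows 3-7   cols 10-14 -> D (25)    rows 3-6  cols 15-19 -> E (20)
    rows 5-9   cols 0-2  -> F (15)     rows 5-8  cols 3-5   -> G (12)
    rows 5-7   cols 6-7  -> H (6)      rows 5-6  cols 8-9   -> I (4)
    row 7      col 8     -> J (1)      everything else      -> A (237)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .areal_data import AdjacencyGraph, ArealTimeSeries, inverse_transform, standardize_times
from .car_model import car_covariance
from .partition_prior import SpatialPartition

__all__ = [
    "SimulationTruth",
    "make_grid",
    "fixture_partitions",
    "simulate",
    "simulate_counts",
    "simulate_partitioned",
    "SEPARATIONS",
]

# gaps between consecutive distinct cluster means, by separation setting
SEPARATIONS = {
    "high": {"delta_alpha": 2.0, "delta_beta": 1.5},
    "medium": {"delta_alpha": 1.0, "delta_beta": 0.75},
    "low": {"delta_alpha": 0.5, "delta_beta": 0.35},
}
DEFAULT_SIGMA2 = 1.0
DEFAULT_CAR_SCALE = 0.01  # within-cluster CAR variance as a multiple of sigma^2


@dataclass
class SimulationTruth:
    gamma_alpha_true: SpatialPartition
    gamma_beta_true: SpatialPartition
    alpha_true: np.ndarray
    beta_true: np.ndarray
    alpha_bar: np.ndarray
    beta_bar: np.ndarray
    sigma2: float
    setting: str


def make_grid(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency grid: units share an edge with their horizontal and
    vertical neighbors.  Unit index = row * cols + col."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be at least 1")
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    return AdjacencyGraph.from_edges(edges, rows * cols)


def _rect(rows, cols, r0, r1, c0, c1):
    """Unit indices of the inclusive block [r0, r1] x [c0, c1]."""
    return [r * cols + c for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]


def fixture_partitions() -> tuple[SpatialPartition, SpatialPartition]:
    """The fixed 20 x 20 ground-truth partitions (see module docstring)."""
    rows = cols = 20
    n = rows * cols
    ga = np.zeros(n, dtype=int)  # cluster A (237) is the background
    blocks = [
        (0, 4, 0, 9),  # B, 50
        (0, 2, 10, 19),  # C, 30
        (3, 7, 10, 14),  # D, 25
        (3, 6, 15, 19),  # E, 20
        (5, 9, 0, 2),  # F, 15
        (5, 8, 3, 5),  # G, 12
        (5, 7, 6, 7),  # H, 6
        (5, 6, 8, 9),  # I, 4
        (7, 7, 8, 8),  # J, 1
    ]
    for label, (r0, r1, c0, c1) in enumerate(blocks, start=1):
        ga[_rect(rows, cols, r0, r1, c0, c1)] = label
    gb = np.zeros(n, dtype=int)  # remainder cluster, 188
    gb[_rect(rows, cols, 0, 19, 0, 4)] = 1  # 100
    gb[_rect(rows, cols, 0, 19, 5, 9)] = 2  # 100
    gb[_rect(rows, cols, 0, 2, 10, 13)] = 3  # 12
    return SpatialPartition(ga), SpatialPartition(gb)


def _draw_car_within(partition, graph, cluster_means, scale, rho, rng) -> np.ndarray:
    """Draw unit-level parameters: CAR(mean_k, scale, W_k) within cluster k."""
    theta = np.empty(partition.n_units)
    for k, members in enumerate(partition.clusters()):
        W_sub = graph.W[np.ix_(members, members)].astype(float)
        cov = scale * car_covariance(W_sub, rho)
        theta[members] = rng.multivariate_normal(
            np.full(members.size, cluster_means[k]), cov, method="cholesky"
        )
    return theta


def simulate_partitioned(
    graph: AdjacencyGraph,
    gamma_alpha: SpatialPartition,
    gamma_beta: SpatialPartition,
    alpha_bar,
    beta_bar,
    sigma2: float = DEFAULT_SIGMA2,
    T: int = 12,
    car_scale: float = DEFAULT_CAR_SCALE,
    rho: float = 0.9,
    seed: int = 0,
    setting: str = "custom",
) -> tuple[ArealTimeSeries, SimulationTruth]:
    """Generate a Gaussian panel from arbitrary partitions and cluster means
    (the engine behind :func:`simulate`; also handy for small test graphs)."""
    rng = np.random.default_rng(seed)
    alpha_bar = np.asarray(alpha_bar, dtype=float)
    beta_bar = np.asarray(beta_bar, dtype=float)
    alpha = _draw_car_within(gamma_alpha, graph, alpha_bar, car_scale * sigma2, rho, rng)
    beta = _draw_car_within(gamma_beta, graph, beta_bar, car_scale * sigma2, rho, rng)
    x = standardize_times(T)
    mean = alpha[:, None] + beta[:, None] * x[None, :]
    y = mean + rng.normal(scale=np.sqrt(sigma2), size=mean.shape)
    data = ArealTimeSeries(y=y, x=x, areas=np.ones(graph.n_units), graph=graph)
    truth = SimulationTruth(
        gamma_alpha_true=gamma_alpha,
        gamma_beta_true=gamma_beta,
        alpha_true=alpha,
        beta_true=beta,
        alpha_bar=alpha_bar,
        beta_bar=beta_bar,
        sigma2=sigma2,
        setting=setting,
    )
    return data, truth


def simulate(setting: str = "high", seed: int = 0, sigma2: float = DEFAULT_SIGMA2,
             car_scale: float = DEFAULT_CAR_SCALE, rho: float = 0.9,
             T: int = 12) -> tuple[ArealTimeSeries, SimulationTruth]:
    """One replicate of the 20 x 20 reference design at the given separation.

    The ten intercept clusters share five distinct means, two clusters per
    mean, spaced ``delta_alpha`` apart and centered at zero; the four slope
    clusters get four distinct means spaced ``delta_beta`` apart.
    """
    if setting not in SEPARATIONS:
        raise ValueError(f"setting must be one of {sorted(SEPARATIONS)}")
    d = SEPARATIONS[setting]
    ga, gb = fixture_partitions()
    graph = make_grid(20, 20)
    # five distinct values, two clusters per value; the two clusters sharing
    # a mean are never spatially adjacent, so the 10-cluster partition stays
    # identifiable (adjacent same-mean clusters would collapse a posteriori)
    levels = (np.arange(5) - 2.0) * d["delta_alpha"]
    alpha_bar = levels[[0, 1, 2, 3, 4, 2, 3, 4, 1, 0]]
    beta_bar = (np.arange(4) - 1.5) * d["delta_beta"]
    return simulate_partitioned(
        graph, ga, gb, alpha_bar, beta_bar,
        sigma2=sigma2, T=T, car_scale=car_scale, rho=rho, seed=seed, setting=setting,
    )


def simulate_scaled(setting: str = "medium", seed: int = 0, rows: int = 10,
                    cols: int = 10, T: int = 12, sigma2: float = DEFAULT_SIGMA2,
                    car_scale: float = DEFAULT_CAR_SCALE,
                    rho: float = 0.9) -> tuple[ArealTimeSeries, SimulationTruth]:
    """A scaled-down analogue of the reference design for quick studies.

    On a rows x cols grid, the intercept partition has four quadrant
    clusters (distinct means spaced ``delta_alpha``) and the slope partition
    has three vertical bands (distinct means spaced ``delta_beta``).
    """
    if setting not in SEPARATIONS:
        raise ValueError(f"setting must be one of {sorted(SEPARATIONS)}")
    d = SEPARATIONS[setting]
    graph = make_grid(rows, cols)
    ga = np.empty(rows * cols, dtype=int)
    gb = np.empty(rows * cols, dtype=int)
    for i in range(rows * cols):
        r, c = divmod(i, cols)
        ga[i] = (r >= rows // 2) * 2 + (c >= cols // 2)
        gb[i] = (c >= cols // 3) + (c >= 2 * cols // 3)
    alpha_bar = (np.arange(4) - 1.5) * d["delta_alpha"]
    beta_bar = (np.arange(3) - 1.0) * d["delta_beta"]
    return simulate_partitioned(
        graph, SpatialPartition(ga), SpatialPartition(gb), alpha_bar, beta_bar,
        sigma2=sigma2, T=T, car_scale=car_scale, rho=rho, seed=seed, setting=setting,
    )


def simulate_counts(data: ArealTimeSeries) -> np.ndarray:
    """Convert simulated transformed densities into event counts,
    ``c = round(A * sinh(y + log 2))`` floored at zero (with the unit-area
    convention of the simulation this is ``round(sinh(y + log 2))``)."""
    return inverse_transform(data.y, data.areas)
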