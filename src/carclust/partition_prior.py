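"""Spatial partitions and the truncated Ewens-Pitman partition prior.

A *spatial partition* of the areal units is one in which every cluster
induces a connected subgraph of the adjacency graph.  The prior over
partitions is the Ewens-Pitman exchangeable partition probability function
(the Chinese-restaurant EPPF), truncated to spatial partitions:

    pi(gamma) ∝ eta^K * prod_k (n_k - 1)! * 1(gamma spatial)

It favors a small number of large clusters; untruncated, it induces on the
order of eta*log(N) clusters on average.  The truncation normalizer is
intractable but constant on a fixed graph, so all downstream comparisons use
unnormalized log probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .areal_data import AdjacencyGraph

__all__ = [
    "SpatialPartition",
    "canonical_labels",
    "log_ep_prior",
    "expected_clusters_untruncated",
]


def canonical_labels(assignment) -> np.ndarray:
    """Relabel cluster labels to 0..K-1 in order of first occurrence."""
    assignment = np.asarray(assignment)
    _, canon = np.unique(assignment, return_inverse=True)
    # np.unique orders labels by value; re-map to first-occurrence order
    first = {}
    out = np.empty(len(assignment), dtype=np.int64)
    nxt = 0
    for i, lab in enumerate(canon):
        if lab not in first:
            first[lab] = nxt
            nxt += 1
        out[i] = first[lab]
    return out


@dataclass(frozen=True)
class SpatialPartition:
    """Assignment of N units to K clusters, canonically labelled.

    Labels are 0..K-1 in order of first occurrence, so two partitions are
    equal iff their ``assignment`` tuples are equal.
    """

    assignment: tuple

    def __init__(self, assignment):
        labels = canonical_labels(np.asarray(assignment, dtype=np.int64))
        object.__setattr__(self, "assignment", tuple(int(v) for v in labels))

    @property
    def n_units(self) -> int:
        return len(self.assignment)

    @property
    def n_clusters(self) -> int:
        return max(self.assignment) + 1 if self.assignment else 0

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_clusters)

    def clusters(self) -> list[np.ndarray]:
        """Cluster member indices, ordered by cluster label."""
        a = np.asarray(self.assignment)
        return [np.flatnonzero(a == k) for k in range(self.n_clusters)]

    def is_spatial(self, graph: AdjacencyGraph) -> bool:
        """True iff every cluster induces a connected subgraph."""
        from .partition_moves import connected_components

        if graph.n_units != self.n_units:
            raise ValueError("partition and graph sizes differ")
        return all(
            len(connected_components(members, graph)) == 1
            for members in self.clusters()
        )

    @classmethod
    def single_cluster(cls, n: int) -> "SpatialPartition":
        return cls(np.zeros(n, dtype=int))

    @classmethod
    def singletons(cls, n: int) -> "SpatialPartition":
        return cls(np.arange(n))


def log_ep_prior(
    partition: SpatialPartition,
    eta: float,
    graph: AdjacencyGraph | None = None,
) -> float:
    """Unnormalized log Ewens-Pitman mass ``K log eta + sum_k log (n_k-1)!``.

    If ``graph`` is supplied and some cluster is disconnected, returns -inf
    (the partition lies outside the spatial-partition support).
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if graph is not None and not partition.is_spatial(graph):
        return -np.inf
    sizes = partition.sizes
    return float(partition.n_clusters * np.log(eta) + gammaln(sizes).sum())


def expected_clusters_untruncated(eta: float, N: int) -> float:
    """Asymptotic mean cluster count ``eta * log N`` of the untruncated prior.

    Used to size the k-means initialization grid.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    return float(eta * np.log(N))
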