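"""Local transitions on spatially connected partitions.

Fine moves reallocate a single unit (island: to a new singleton; border:
across a cluster boundary).  Coarse moves reallocate many units at once
(merge two adjacent clusters; split one cluster into up to ``max_parts``
pieces by 1-D k-means on the running unit-level estimates; split-and-merge).
Whenever removing units disconnects a donor cluster, its connected
components become separate clusters, so every generated candidate is again
a spatial partition.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .areal_data import AdjacencyGraph
from .partition_prior import SpatialPartition

__all__ = [
    "MoveCandidate",
    "connected_components",
    "island_moves",
    "border_moves",
    "merge_moves",
    "split_moves",
    "split_merge_moves",
    "all_island_sweep",
    "enumerate_spatial_partitions",
]


@dataclass(frozen=True)
class MoveCandidate:
    kind: str
    source: tuple
    partition: SpatialPartition


def connected_components(units, graph: AdjacencyGraph) -> list[list[int]]:
    """Maximal connected subsets of ``units`` in the induced subgraph.

    Components are each sorted and ordered by their smallest member, so the
    output is deterministic.
    """
    unit_set = set(int(u) for u in units)
    if not unit_set:
        raise ValueError("units must be nonempty")
    comps = []
    remaining = set(unit_set)
    for start in sorted(unit_set):
        if start not in remaining:
            continue
        comp = {start}
        remaining.discard(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in graph.neighbors(u):
                v = int(v)
                if v in remaining:
                    remaining.discard(v)
                    comp.add(v)
                    queue.append(v)
        comps.append(sorted(comp))
    return comps


def _reassign(partition, graph, unit, new_label):
    """Move ``unit`` to cluster ``new_label`` (or a fresh singleton if None),
    splitting the donor cluster into components if it disconnects."""
    labels = np.asarray(partition.assignment).copy()
    old = labels[unit]
    K = partition.n_clusters
    labels[unit] = K + 1 if new_label is None else new_label
    donor_rest = np.flatnonzero(labels == old)
    if donor_rest.size:
        for j, comp in enumerate(connected_components(donor_rest, graph)):
            if j > 0:
                labels[comp] = K + 2 + j
    return SpatialPartition(labels)


def island_moves(partition, graph, estimates, quantile: float = 0.05):
    """Singleton-creation moves for units in the tails of their cluster.

    A unit is eligible if its running estimate is at or below the
    ``quantile`` or at or beyond the ``1-quantile`` empirical quantile of
    estimates within its cluster; clusters of size one are skipped and
    clusters of size two make both members eligible.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must be in (0, 0.5]")
    estimates = np.asarray(estimates, dtype=float)
    out = []
    for k, members in enumerate(partition.clusters()):
        if members.size < 2:
            continue
        vals = estimates[members]
        if members.size == 2:
            eligible = members
        else:
            lo, hi = np.quantile(vals, [quantile, 1.0 - quantile])
            eligible = members[(vals <= lo) | (vals >= hi)]
        for u in eligible:
            out.append(
                MoveCandidate("island", (int(u),), _reassign(partition, graph, int(u), None))
            )
    return out


def border_moves(partition, graph):
    """Move one boundary unit into an adjacent cluster (one candidate per
    distinct adjacent foreign cluster)."""
    labels = np.asarray(partition.assignment)
    out = []
    for u in range(partition.n_units):
        foreign = sorted({int(labels[v]) for v in graph.neighbors(u)} - {int(labels[u])})
        for k in foreign:
            out.append(MoveCandidate("border", (u, k), _reassign(partition, graph, u, k)))
    return out


def _adjacent_clusters(labels, graph):
    """Set of unordered label pairs of spatially adjacent clusters."""
    pairs = set()
    for u, v in graph.edges():
        a, b = int(labels[u]), int(labels[v])
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    return pairs


def merge_moves(partition, graph, grand_means):
    """Merge each cluster with its spatially adjacent cluster of closest
    grand mean; symmetric duplicates are removed."""
    grand_means = np.asarray(grand_means, dtype=float)
    labels = np.asarray(partition.assignment)
    adjacency = _adjacent_clusters(labels, graph)
    nbrs: dict[int, list[int]] = {}
    for a, b in adjacency:
        nbrs.setdefault(a, []).append(b)
        nbrs.setdefault(b, []).append(a)
    chosen = set()
    for k, ns in nbrs.items():
        gaps = np.abs(grand_means[ns] - grand_means[k])
        kp = ns[int(np.argmin(gaps))]
        chosen.add((min(k, kp), max(k, kp)))
    out = []
    for a, b in sorted(chosen):
        merged = labels.copy()
        merged[merged == b] = a
        out.append(MoveCandidate("merge", (a, b), SpatialPartition(merged)))
    return out


def _kmeans_1d(values: np.ndarray, m: int, iters: int = 25) -> np.ndarray:
    """Deterministic 1-D Lloyd's algorithm: centers initialized at m evenly
    spaced empirical quantiles; ties assigned to the lower center index."""
    centers = np.quantile(values, np.linspace(0.0, 1.0, m))
    for _ in range(iters):
        d = np.abs(values[:, None] - centers[None, :])
        assign = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
        new_centers = centers.copy()
        for j in range(m):
            mask = assign == j
            if mask.any():
                new_centers[j] = values[mask].mean()
        if np.allclose(new_centers, centers):
            break
        centers = new_centers
    return np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)


def _split_cluster(partition, graph, k, members, sub_assign):
    """Partition with cluster ``k`` replaced by the connectivity-repaired
    pieces of ``sub_assign``; returns (partition, piece_unit_lists)."""
    labels = np.asarray(partition.assignment).copy()
    base = partition.n_clusters
    pieces = []
    nxt = 0
    for j in range(sub_assign.max() + 1):
        part_units = members[sub_assign == j]
        if part_units.size == 0:
            continue
        for comp in connected_components(part_units, graph):
            pieces.append(comp)
            labels[comp] = base + nxt
            nxt += 1
    return SpatialPartition(labels), pieces


def split_moves(partition, graph, unit_estimates, max_parts: int = 5):
    """Subdivide each cluster into m = 2..max_parts pieces by 1-D k-means on
    the within-cluster estimates, with connectivity repair (so a candidate
    may contain more than m pieces)."""
    if max_parts < 2:
        raise ValueError("max_parts must be at least 2")
    unit_estimates = np.asarray(unit_estimates, dtype=float)
    out, seen = [], set()
    for k, members in enumerate(partition.clusters()):
        if members.size < 2:
            continue
        vals = unit_estimates[members]
        for m in range(2, min(max_parts, members.size) + 1):
            sub = _kmeans_1d(vals, m)
            cand, _ = _split_cluster(partition, graph, k, members, sub)
            if cand == partition or cand.assignment in seen:
                continue
            seen.add(cand.assignment)
            out.append(MoveCandidate("split", (k, m), cand))
    return out


def split_merge_moves(partition, graph, unit_estimates, grand_means, max_parts: int = 5):
    """Split a cluster, then merge every resulting piece into the spatially
    adjacent *other* cluster whose grand mean is closest; pieces with no
    foreign neighbor remain separate clusters."""
    grand_means = np.asarray(grand_means, dtype=float)
    unit_estimates = np.asarray(unit_estimates, dtype=float)
    labels0 = np.asarray(partition.assignment)
    out, seen = [], set()
    for k, members in enumerate(partition.clusters()):
        if members.size < 2:
            continue
        vals = unit_estimates[members]
        for m in range(2, min(max_parts, members.size) + 1):
            sub = _kmeans_1d(vals, m)
            _, pieces = _split_cluster(partition, graph, k, members, sub)
            if len(pieces) < 2:
                continue
            labels = labels0.copy().astype(np.int64)
            base = partition.n_clusters
            for j, comp in enumerate(pieces):
                labels[comp] = base + j
            changed = False
            for j, comp in enumerate(pieces):
                foreign = set()
                for u in comp:
                    for v in graph.neighbors(u):
                        lv = int(labels0[v])
                        if lv != k:
                            foreign.add(lv)
                if foreign:
                    fs = sorted(foreign)
                    piece_mean = unit_estimates[comp].mean()
                    gaps = np.abs(grand_means[fs] - piece_mean)
                    target = fs[int(np.argmin(gaps))]
                    labels[comp] = target
                    changed = True
            if not changed:
                continue
            cand = SpatialPartition(labels)
            if cand == partition or cand.assignment in seen:
                continue
            seen.add(cand.assignment)
            out.append(MoveCandidate("split_merge", (k, m), cand))
    return out


def all_island_sweep(partition, graph):
    """All N single-unit-to-new-singleton moves (existing singletons are
    no-ops and skipped); used to certify local convergence."""
    sizes = partition.sizes
    labels = np.asarray(partition.assignment)
    out = []
    for u in range(partition.n_units):
        if sizes[labels[u]] < 2:
            continue
        out.append(
            MoveCandidate("full_island_sweep", (u,), _reassign(partition, graph, u, None))
        )
    return out


def enumerate_spatial_partitions(graph: AdjacencyGraph) -> list[SpatialPartition]:
    """All spatial partitions of a small graph (exhaustive; intended for
    N <= 10 where the Bell number is manageable)."""
    n = graph.n_units
    if n > 12:
        raise ValueError("exhaustive enumeration is limited to small graphs")
    results = []

    def recurse(i, clusters):
        if i == n:
            labels = np.empty(n, dtype=int)
            for k, members in enumerate(clusters):
                labels[list(members)] = k
            p = SpatialPartition(labels)
            if p.is_spatial(graph):
                results.append(p)
            return
        for c in clusters:
            c.add(i)
            recurse(i + 1, clusters)
            c.remove(i)
        clusters.append({i})
        recurse(i + 1, clusters)
        clusters.pop()

    recurse(0, [])
    return results
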