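"""Containers and I/O for areal time-series data.

The response modelled throughout the package is a *transformed density*:
raw event counts ``c`` in areal units of area ``A`` are mapped through the
inverse hyperbolic sine transform ``y = asinh(c/A) - log 2``, which behaves
like a log transform for large densities but is finite at zero counts.
Time is a standardized index with mean zero and unit sample variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AdjacencyGraph",
    "ArealTimeSeries",
    "transform_density",
    "inverse_transform",
    "standardize_times",
    "read_areal_csv",
    "read_adjacency",
    "write_results",
]

LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class AdjacencyGraph:
    """Binary symmetric neighborhood structure over ``n_units`` areal units."""

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(W, W.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.trace(np.abs(W)) != 0:
            raise ValueError("adjacency matrix must have zero diagonal")
        if not np.isin(W, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "W", W.astype(np.int8))
        # neighbor index lists, precomputed once; used heavily by the move
        # generators and connectivity checks
        nbrs = tuple(np.flatnonzero(W[i]) for i in range(W.shape[0]))
        object.__setattr__(self, "_neighbors", nbrs)

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self._neighbors[i]

    @classmethod
    def from_edges(cls, edges, n_units: int) -> "AdjacencyGraph":
        W = np.zeros((n_units, n_units), dtype=np.int8)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on unit {u}")
            W[u, v] = W[v, u] = 1
        return cls(W)

    def edges(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.W))
        return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class ArealTimeSeries:
    """N x T panel of transformed densities with a standardized time covariate.

    ``y`` holds transformed densities, ``x`` the standardized time index
    (sum zero, sample variance one), ``areas`` the unit areas used for the
    count<->density transforms.  ``graph`` optionally carries the adjacency
    structure the spatial model is defined on.
    """

    y: np.ndarray
    x: np.ndarray
    areas: np.ndarray
    counts: np.ndarray | None = None
    graph: AdjacencyGraph | None = None
    unit_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be an N x T matrix")
        n, t = self.y.shape
        if t < 3:
            raise ValueError("need at least T=3 time points")
        if self.x.shape != (t,):
            raise ValueError("x must have length T")
        if self.areas.shape != (n,):
            raise ValueError("areas must have length N")
        if np.any(~np.isfinite(self.y)):
            raise ValueError("missing or non-finite responses are unsupported")
        if abs(self.x.sum()) > 1e-8 * t or abs(np.var(self.x, ddof=1) - 1.0) > 1e-8:
            raise ValueError("x must be standardized (mean 0, sample variance 1)")
        if self.graph is not None and self.graph.n_units != n:
            raise ValueError("graph size does not match number of units")

    @property
    def n_units(self) -> int:
        return self.y.shape[0]

    @property
    def n_times(self) -> int:
        return self.y.shape[1]


def transform_density(counts, areas) -> np.ndarray:
    """Inverse hyperbolic sine transform of count densities.

    ``y = asinh(c / A) - log 2`` elementwise; defined (and equal to -log 2)
    at zero counts.
    """
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if np.any(areas <= 0):
        raise ValueError("areas must be strictly positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    dens = counts / areas[..., None] if counts.ndim == 2 else counts / areas
    return np.arcsinh(dens) - LOG2


def inverse_transform(ystar, areas) -> np.ndarray:
    """Map transformed densities back to counts: nearest integer of
    ``A * sinh(y + log 2)``, floored at zero."""
    ystar = np.asarray(ystar, dtype=float)
    areas = np.asarray(areas, dtype=float)
    dens = np.sinh(ystar + LOG2)
    c = areas[..., None] * dens if ystar.ndim == 2 else areas * dens
    return np.maximum(np.rint(c), 0.0).astype(np.int64)


def standardize_times(T: int) -> np.ndarray:
    """Standardized time covariate from raw indices ``0..T-1``.

    Centered and scaled by the sample standard deviation (denominator T-1),
    so that ``sum(x) = 0`` and ``sum(x**2) = T - 1``.
    """
    if T < 2:
        raise ValueError("need at least two time points")
    t = np.arange(T, dtype=float)
    t -= t.mean()
    return t / np.sqrt(np.sum(t**2) / (T - 1))


def read_areal_csv(path, fmt: str = "long") -> ArealTimeSeries:
    """Read a panel of counts from CSV.

    ``long`` format has columns ``unit_id,time,count[,area]`` (area defaults
    to 1 and must be constant per unit); ``wide`` has one row per unit with an
    ``unit_id`` column, an optional ``area`` column, and T numeric columns.
    Units are indexed in order of first appearance.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    if fmt == "long":
        required = {"unit_id", "time", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"long CSV must have columns {sorted(required)}")
        unit_ids = list(dict.fromkeys(df["unit_id"]))
        if "area" not in df.columns:
            df = df.assign(area=1.0)
        areas = df.groupby("unit_id", sort=False)["area"].agg(["min", "max"])
        if (areas["min"] != areas["max"]).any():
            raise ValueError("area must be constant within a unit")
        counts = df.pivot_table(
            index="unit_id", columns="time", values="count", sort=False
        ).reindex(unit_ids)
        if counts.isna().any().any():
            raise ValueError("ragged time series: every unit needs every time point")
        counts = counts[sorted(counts.columns)].to_numpy()
        area_vec = areas["min"].reindex(unit_ids).to_numpy(dtype=float)
    elif fmt == "wide":
        if "unit_id" not in df.columns:
            raise ValueError("wide CSV must have a unit_id column")
        unit_ids = list(df["unit_id"])
        area_vec = (
            df["area"].to_numpy(dtype=float)
            if "area" in df.columns
            else np.ones(len(df))
        )
        value_cols = [c for c in df.columns if c not in ("unit_id", "area")]
        counts = df[value_cols].to_numpy(dtype=float)
        if np.isnan(counts).any():
            raise ValueError("missing values in wide CSV")
    else:
        raise ValueError("fmt must be 'long' or 'wide'")
    counts = np.asarray(counts)
    T = counts.shape[1]
    y = transform_density(counts, area_vec)
    return ArealTimeSeries(
        y=y,
        x=standardize_times(T),
        areas=area_vec,
        counts=counts.astype(np.int64),
        unit_ids=unit_ids,
    )


def read_adjacency(path, unit_ids: list[str] | None = None) -> AdjacencyGraph:
    """Read adjacency from a two-column edge list or a dense 0/1 matrix CSV.

    A file whose rows all have the same length > 2 is treated as a dense
    matrix; otherwise as an undirected edge list of opaque unit ids, mapped
    to indices via ``unit_ids`` (or order of first appearance).
    """
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] > 2 or (df.shape[1] == df.shape[0] == 2 and df.isin(["0", "1"]).all().all()):
        W = df.to_numpy(dtype=float)
        if not np.array_equal(W, W.T):
            raise ValueError("dense adjacency must be symmetric")
        return AdjacencyGraph(W.astype(np.int8))
    if df.iloc[0].tolist() == ["u", "v"]:
        df = df.iloc[1:]
    if unit_ids is None:
        unit_ids = list(dict.fromkeys(pd.concat([df[0], df[1]])))
    index = {u: i for i, u in enumerate(unit_ids)}
    unknown = set(df[0]) | set(df[1])
    unknown -= set(index)
    if unknown:
        raise ValueError(f"unknown unit ids in edge list: {sorted(unknown)[:5]}")
    edges = {(min(index[u], index[v]), max(index[u], index[v])) for u, v in zip(df[0], df[1])}
    return AdjacencyGraph.from_edges(sorted(edges), len(unit_ids))


def write_results(prefix, estimates: pd.DataFrame, particle_set=None) -> None:
    """Write estimates CSV (``<prefix>_estimates.csv``) and, if given, the
    particle set JSON (``<prefix>_particles.json``)."""
    estimates.to_csv(f"{prefix}_estimates.csv", index=False)
    if particle_set is not None:
        with open(f"{prefix}_particles.json", "w") as fh:
            json.dump(particle_set.to_dict(), fh, indent=1)
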