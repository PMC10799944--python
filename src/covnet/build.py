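"""Construction of structural covariance networks.

A group's residualized morphometry table is turned into a 68×68
interregional Pearson correlation matrix, optionally Fisher z-transformed,
and binarized over a proportional-threshold ("sparsity") sweep: at density
``d`` the ``round(d · n(n-1)/2)`` strongest edges are kept.  Because the
top-k sets at increasing k are nested, the sweep forms a nested ensemble of
unweighted, undirected graphs.

Edges are ranked by signed association strength by default (strongest
positive correlations first), the common covariance-network convention at
thresholds up to 40%; ranking by absolute value is available for
sensitivity analyses.  Ties at the cut are broken by lexicographic node
pair order so every graph is deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

from .morpho import MorphometryTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "BinaryGraph",
    "GraphEnsemble",
    "correlation_matrix",
    "fisher_z",
    "edges_at_density",
    "edge_order",
    "binarize_at_density",
    "build_ensemble",
    "min_connected_density",
    "density_grid",
]

DEFAULT_DENSITY_MIN = 0.06
DEFAULT_DENSITY_MAX = 0.40
DEFAULT_DENSITY_STEP = 0.01


def density_grid(
    density_min: float = DEFAULT_DENSITY_MIN,
    density_max: float = DEFAULT_DENSITY_MAX,
    density_step: float = DEFAULT_DENSITY_STEP,
) -> np.ndarray:
    """The threshold grid; defaults to 0.06:0.01:0.40 (35 densities)."""
    if not (0 < density_min <= density_max < 1):
        raise ValueError("densities must satisfy 0 < min <= max < 1")
    count = int(round((density_max - density_min) / density_step)) + 1
    grid = density_min + density_step * np.arange(count)
    return np.round(grid, 10)


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric interregional association matrix (diagonal stored as 0)."""

    values: np.ndarray
    scale: str = "pearson_r"  # "pearson_r" | "fisher_z"
    labels: tuple[str, ...] | None = None
    measure: str = ""
    group: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        values = np.array(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("association matrix must be square")
        if not np.allclose(values, values.T, atol=1e-12, equal_nan=True):
            raise ValueError("association matrix must be symmetric")
        np.fill_diagonal(values, 0.0)
        if self.scale == "pearson_r":
            off = values[~np.eye(values.shape[0], dtype=bool)]
            if np.any(np.abs(off) > 1 + 1e-12):
                raise ValueError("pearson correlations must lie in [-1, 1]")
        elif self.scale != "fisher_z":
            raise ValueError(f"unknown scale {self.scale!r}")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Unweighted undirected graph as a dense 0/1 adjacency matrix."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self) -> None:
        adj = np.array(self.adjacency, dtype=np.uint8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-loops are not allowed")
        adj.flags.writeable = False
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def correlation_matrix(
    table: MorphometryTable, allow_unresidualized: bool = False
) -> AssociationMatrix:
    """Interregional Pearson correlations of a group's regional values."""
    if not table.residualized and not allow_unresidualized:
        logger.warning(
            "correlating raw values (covariates not removed); pass "
            "allow_unresidualized=True to silence"
        )
    stds = table.values.std(axis=0)
    if np.any(stds == 0):
        region = table.atlas.region_ids[int(np.argmax(stds == 0))]
        raise ValueError(
            f"region {region!r} has zero variance across subjects; "
            "its correlations are undefined"
        )
    corr = np.corrcoef(table.values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return AssociationMatrix(
        values=corr,
        scale="pearson_r",
        labels=table.atlas.region_ids,
        measure=table.measure,
        group=table.group,
        timepoint=table.timepoint,
    )


def fisher_z(m: AssociationMatrix) -> AssociationMatrix:
    """Entrywise Fisher transform z = atanh(r); strictly monotone in r."""
    if m.scale != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    off = ~np.eye(m.n_nodes, dtype=bool)
    if np.any(np.abs(m.values[off]) >= 1):
        i, j = np.argwhere((np.abs(m.values) >= 1) & off)[0]
        raise ValueError(
            f"|r| = 1 between regions {i} and {j}: Fisher z is infinite "
            "(duplicated regions?)"
        )
    z = np.arctanh(m.values)
    np.fill_diagonal(z, 0.0)
    return replace(m, values=z, scale="fisher_z")


def edges_at_density(n_nodes: int, density: float) -> int:
    """Edge count at a proportional threshold: round(d·n(n-1)/2), half away from 0."""
    if not (0 < density < 1):
        raise ValueError(f"density must lie in (0, 1), got {density}")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(density * n_pairs + 0.5))


def edge_order(
    m: AssociationMatrix, absolute: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """All node pairs ranked strongest-first, ties broken lexicographically."""
    n = m.n_nodes
    iu = np.triu_indices(n, 1)
    vals = m.values[iu]
    if absolute:
        vals = np.abs(vals)
    # iu enumerates pairs in lexicographic order; a stable sort on the
    # negated values therefore breaks ties by (i, j).
    order = np.argsort(-vals, kind="stable")
    return iu[0][order].astype(np.int64), iu[1][order].astype(np.int64)


def binarize_at_density(
    m: AssociationMatrix, density: float, absolute: bool = False
) -> BinaryGraph:
    """Keep the k strongest edges, where k = edges_at_density(n, density)."""
    k = edges_at_density(m.n_nodes, density)
    oi, oj = edge_order(m, absolute=absolute)
    if k > oi.size:
        raise ValueError(f"{k} edges requested but only {oi.size} pairs exist")
    adj = np.zeros((m.n_nodes, m.n_nodes), dtype=np.uint8)
    adj[oi[:k], oj[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, density=density)


@dataclass(frozen=True)
class GraphEnsemble:
    """Nested binary graphs over a density grid, stored as a ranked edge list.

    Graph ``t`` consists of the first ``edge_counts[t]`` entries of the
    ranked pair list, so nestedness across densities holds by construction.
    """

    densities: np.ndarray
    edge_counts: np.ndarray
    order_i: np.ndarray
    order_j: np.ndarray
    n_nodes: int
    labels: tuple[str, ...] | None = None
    measure: str = ""
    group: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")
        if len(self.densities) != len(self.edge_counts):
            raise ValueError("densities and edge_counts must align")

    def __len__(self) -> int:
        return len(self.densities)

    def graph(self, index: int) -> BinaryGraph:
        k = int(self.edge_counts[index])
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=np.uint8)
        adj[self.order_i[:k], self.order_j[:k]] = 1
        adj |= adj.T
        return BinaryGraph(adjacency=adj, density=float(self.densities[index]))

    def __iter__(self) -> Iterator[BinaryGraph]:
        return (self.graph(t) for t in range(len(self)))


def build_ensemble(
    m: AssociationMatrix,
    densities: Sequence[float] | None = None,
    absolute: bool = False,
) -> GraphEnsemble:
    """Binarize an association matrix over the density grid (nested sweep)."""
    grid = np.asarray(densities if densities is not None else density_grid())
    oi, oj = edge_order(m, absolute=absolute)
    ks = np.array([edges_at_density(m.n_nodes, d) for d in grid], dtype=np.int64)
    if ks[-1] > oi.size:
        raise ValueError("density grid requests more edges than pairs available")
    return GraphEnsemble(
        densities=grid,
        edge_counts=ks,
        order_i=oi,
        order_j=oj,
        n_nodes=m.n_nodes,
        labels=m.labels,
        measure=m.measure,
        group=m.group,
        timepoint=m.timepoint,
    )


def min_connected_density(
    m: AssociationMatrix, densities: Sequence[float] | None = None
) -> float | None:
    """Smallest grid density whose binarized graph is a single component.

    Returns None when no grid density connects the network.  A warning is
    logged when the answer exceeds the lowest grid density, since the sweep
    then contains disconnected graphs.
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import csr_matrix

    ens = build_ensemble(m, densities=densities)
    for t in range(len(ens)):
        g = ens.graph(t)
        n_comp, _ = connected_components(
            csr_matrix(g.adjacency), directed=False
        )
        if n_comp == 1:
            d = float(ens.densities[t])
            if t > 0:
                logger.warning(
                    "network only becomes fully connected at density %.3f; "
                    "lower grid densities yield disconnected graphs",
                    d,
                )
            return d
    logger.warning("network is disconnected at every grid density")
    return None
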