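"""Graph-theoretic network measures on binary undirected graphs.

Implements the integration measures (characteristic path length, global and
nodal efficiency), segregation measures (clustering coefficient, local
efficiency), betweenness centrality, and the small-world indices
gamma = C/C_rand, lambda = L/L_rand and sigma = gamma/lambda, where the
random reference is a degree-preserving Maslov–Sneppen rewiring of the
graph.  A sigma well above 1 marks the small-world regime: lattice-like
clustering combined with random-graph path lengths.

Conventions (shared with the Brain Connectivity Toolbox):

* clustering of a node with degree < 2 is 0;
* efficiency treats unreachable pairs as 1/inf = 0, so it needs no special
  casing on disconnected graphs;
* characteristic path length is computed on the largest connected component
  (with a warning) when the graph is disconnected;
* betweenness is unnormalized, each unordered pair counted once.

Threshold dependence is condensed by integrating each metric's curve over
the density grid with the trapezoidal rule (the AUC statistic).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .build import BinaryGraph, GraphEnsemble

__all__ = [
    "GlobalMetrics",
    "MetricCurve",
    "AUCStat",
    "degree",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "betweenness",
    "random_reference",
    "normalized_global_metrics",
    "auc_over_densities",
    "ensemble_metric_curves",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
]

GLOBAL_METRIC_NAMES = (
    "normalized_path_length",
    "global_efficiency",
    "normalized_clustering",
    "local_efficiency",
    "small_worldness",
)
NODAL_METRIC_NAMES = ("degree", "nodal_efficiency", "betweenness")


def _as_adj(g) -> np.ndarray:
    if isinstance(g, BinaryGraph):
        return np.asarray(g.adjacency)
    adj = np.asarray(g)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("expected a square adjacency matrix or BinaryGraph")
    return adj


@dataclass(frozen=True)
class GlobalMetrics:
    """Raw and normalized graph-level measures of one binary graph."""

    clustering: float
    path_length: float
    global_efficiency: float
    local_efficiency: float
    gamma: float
    lambda_: float
    sigma: float


@dataclass(frozen=True)
class MetricCurve:
    """One metric evaluated along the density grid."""

    metric: str
    densities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.densities) != len(self.values):
            raise ValueError("densities and values must have equal length")


@dataclass(frozen=True)
class AUCStat:
    """Trapezoidal area under a metric curve over the density grid."""

    metric: str
    scope: str
    auc: float


def degree(g) -> np.ndarray:
    return _as_adj(g).sum(axis=1).astype(np.int64)


def clustering_coefficient(g) -> tuple[np.ndarray, float]:
    """Per-node clustering 2·T_i/(k_i(k_i-1)) (0 if k_i < 2) and its mean."""
    bits = K.adjacency_to_bits(_as_adj(g))
    clus, _ = K.clustering_and_degree(bits)
    return clus, float(clus.mean())


def characteristic_path_length(g) -> float:
    """Mean shortest-path distance over reachable ordered pairs.

    Computed within the largest connected component when the graph is
    disconnected (warns).  An edgeless graph has no finite path and is an
    error.
    """
    adj = _as_adj(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    if adj.sum() == 0:
        raise ValueError("graph has no edges; path length is undefined")
    bits = K.adjacency_to_bits(adj)
    _, reach, sumd, root = K.bfs_stats(bits)
    if np.any(reach < n - 1):
        warnings.warn(
            "graph is disconnected; path length computed on the largest "
            "connected component",
            stacklevel=2,
        )
    return float(K.char_path_length(reach, sumd, root, n))


def nodal_efficiency(g) -> np.ndarray:
    """E_i = mean over j != i of 1/d(i, j), with unreachable pairs contributing 0."""
    adj = _as_adj(g)
    if adj.shape[0] < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    eff, _, _, _ = K.bfs_stats(K.adjacency_to_bits(adj))
    return eff


def global_efficiency(g) -> float:
    return float(nodal_efficiency(g).mean())


def local_efficiency(g) -> tuple[np.ndarray, float]:
    """Efficiency of each node's neighbour-induced subgraph (0 if k_i < 2)."""
    eloc = K.local_efficiency_nodes(K.adjacency_to_bits(_as_adj(g)))
    return eloc, float(eloc.mean())


def betweenness(g) -> np.ndarray:
    """Unnormalized shortest-path betweenness, unordered pairs counted once."""
    adj = _as_adj(g)
    if adj.shape[0] < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    return K.betweenness_nodes(K.adjacency_to_bits(adj))


def _edge_arrays(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(adj.shape[0], 1)
    mask = adj[iu, ju] > 0
    return iu[mask].astype(np.int64), ju[mask].astype(np.int64)


def random_reference(g, n_swaps_per_edge: int = 10, seed: int = 0) -> BinaryGraph:
    """Degree-preserving Maslov–Sneppen randomization of a binary graph.

    Attempts ``n_swaps_per_edge × m`` double-edge swaps, rejecting any swap
    that would create a self-loop or multi-edge.  Graphs admitting no legal
    swap (e.g. complete graphs) are returned unchanged with a warning.
    """
    adj = _as_adj(g)
    eu, ev = _edge_arrays(adj)
    if eu.size < 2:
        raise ValueError("rewiring needs at least 2 edges")
    bits = K.adjacency_to_bits(adj)
    nsucc = K.rewire_seeded(
        bits, eu, ev, int(n_swaps_per_edge) * eu.size, int(seed) % 2**31
    )
    if nsucc == 0:
        warnings.warn(
            "no legal double-edge swap was found; returning the input graph",
            stacklevel=2,
        )
    dens = g.density if isinstance(g, BinaryGraph) else float(
        adj.sum() / (adj.shape[0] * (adj.shape[0] - 1))
    )
    return BinaryGraph(
        adjacency=K.bits_to_adjacency(bits, adj.shape[0]), density=dens
    )


def normalized_global_metrics(
    g,
    n_null: int = 100,
    seed: int = 0,
    n_swaps_per_edge: int = 10,
) -> GlobalMetrics:
    """Raw global measures plus gamma, lambda and sigma.

    gamma = C / mean(C of n_null rewired references), lambda likewise for
    the characteristic path length, sigma = gamma / lambda.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    adj = _as_adj(g)
    n = adj.shape[0]
    bits = K.adjacency_to_bits(adj)
    clus, _ = K.clustering_and_degree(bits)
    _, reach, sumd, root = K.bfs_stats(bits)
    eff = nodal_efficiency(adj)
    cmean = float(clus.mean())
    lpath = float(K.char_path_length(reach, sumd, root, n))
    eloc, eloc_mean = local_efficiency(adj)
    cnull = 0.0
    lnull = 0.0
    eu, ev = _edge_arrays(adj)
    for r in range(n_null):
        rbits = bits.copy()
        reu = eu.copy()
        rev = ev.copy()
        K.rewire_seeded(
            rbits, reu, rev, int(n_swaps_per_edge) * eu.size,
            (int(seed) + 104729 * r) % 2**31,
        )
        cn, _ = K.clustering_and_degree(rbits)
        _, rreach, rsumd, rroot = K.bfs_stats(rbits)
        cnull += cn.mean()
        lnull += K.char_path_length(rreach, rsumd, rroot, n)
    cnull /= n_null
    lnull /= n_null
    if cnull == 0 or lnull == 0:
        raise ValueError(
            "mean clustering or path length of the random references is zero; "
            "normalization is undefined"
        )
    gamma = cmean / cnull
    lambda_ = lpath / lnull
    return GlobalMetrics(
        clustering=cmean,
        path_length=lpath,
        global_efficiency=float(eff.mean()),
        local_efficiency=eloc_mean,
        gamma=gamma,
        lambda_=lambda_,
        sigma=gamma / lambda_,
    )


def auc_over_densities(curve: MetricCurve) -> AUCStat:
    """Trapezoidal integral of a metric curve against the density grid."""
    d = np.asarray(curve.densities, dtype=float)
    v = np.asarray(curve.values, dtype=float)
    if d.size < 2:
        raise ValueError("AUC needs at least 2 densities")
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    return AUCStat(
        metric=curve.metric, scope="global", auc=float(np.trapezoid(v, d))
    )


def data_seed(values: np.ndarray, base_seed: int) -> int:
    """Reference-randomization seed derived from the data matrix itself.

    Tying the reference stream to the data (not to call order) makes metric
    curves a pure function of (values, config, base_seed): identical groups
    yield identical curves, and swapping two groups negates every AUC
    difference exactly.
    """
    crc = zlib.crc32(np.ascontiguousarray(values).tobytes())
    return int((crc ^ (int(base_seed) * 2654435761)) % 2**31)


def ensemble_metric_curves(
    ensemble: GraphEnsemble,
    n_null: int = 20,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
    include_nodal: bool = True,
) -> dict[str, object]:
    """All metric curves over a nested density sweep (one kernel pass).

    Returns a dict with a MetricCurve per global metric (raw C/L/Eglob/Eloc
    plus gamma/lambda/sigma when ``n_null > 0``) and, when ``include_nodal``,
    (n_densities × n_nodes) arrays for degree, nodal efficiency and
    betweenness under ``"nodal"``.
    """
    raw, norm, deg_c, eff_c, btw_c = K.ensemble_curves(
        ensemble.order_i,
        ensemble.order_j,
        ensemble.edge_counts,
        ensemble.n_nodes,
        int(n_null),
        int(n_swaps_per_edge),
        int(seed) % 2**31,
        bool(include_nodal),
    )
    d = ensemble.densities
    out: dict[str, object] = {
        "clustering": MetricCurve("clustering", d, raw[0]),
        "path_length": MetricCurve("path_length", d, raw[1]),
        "global_efficiency": MetricCurve("global_efficiency", d, raw[2]),
        "local_efficiency": MetricCurve("local_efficiency", d, raw[3]),
    }
    if n_null > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma = norm[0] / norm[1]
        out["normalized_clustering"] = MetricCurve("normalized_clustering", d, norm[0])
        out["normalized_path_length"] = MetricCurve(
            "normalized_path_length", d, norm[1]
        )
        out["small_worldness"] = MetricCurve("small_worldness", d, sigma)
    if include_nodal:
        out["nodal"] = {
            "degree": deg_c,
            "nodal_efficiency": eff_c,
            "betweenness": btw_c,
        }
    return out
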