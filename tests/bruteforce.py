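"""Independent brute-force graph-metric oracles for small graphs.

Everything here goes through Floyd–Warshall all-pairs distances and direct
shortest-path counting — deliberately different algorithms from the
package's BFS/Brandes kernels — so agreement is a genuine cross-check.
Only meant for n <= ~30.
"""

from __future__ import annotations

import numpy as np


def distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by Floyd–Warshall (inf if unreachable)."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def degree(adj: np.ndarray) -> np.ndarray:
    return adj.sum(axis=1)


def clustering(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = len(nbrs)
        if k < 2:
            continue
        triangles = sum(
            adj[u, v] for a, u in enumerate(nbrs) for v in nbrs[a + 1:]
        )
        out[i] = 2.0 * triangles / (k * (k - 1))
    return out


def components(adj: np.ndarray) -> list[list[int]]:
    d = distances(adj)
    seen: set[int] = set()
    comps = []
    for i in range(adj.shape[0]):
        if i in seen:
            continue
        comp = sorted(np.flatnonzero(np.isfinite(d[i])).tolist())
        comps.append(comp)
        seen.update(comp)
    return comps


def path_length(adj: np.ndarray) -> float:
    """Mean distance over ordered pairs in the largest component.

    Ties between equally large components break toward the one containing
    the smallest node index (the package convention).
    """
    comps = components(adj)
    comps.sort(key=lambda c: (-len(c), c[0]))
    comp = comps[0]
    if len(comp) < 2:
        return 0.0
    d = distances(adj)
    sub = d[np.ix_(comp, comp)]
    mask = ~np.eye(len(comp), dtype=bool)
    return float(sub[mask].mean())


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = distances(adj)
    n = adj.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(adj: np.ndarray) -> float:
    return float(nodal_efficiency(adj).mean())


def local_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) < 2:
            continue
        out[i] = global_efficiency(adj[np.ix_(nbrs, nbrs)])
    return out


def _path_counts(adj: np.ndarray, d: np.ndarray) -> np.ndarray:
    """sigma[s, t]: number of distinct shortest s-t paths, by BFS-layer DP."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        order = np.argsort(d[s])
        for v in order:
            if v == s or not np.isfinite(d[s, v]):
                continue
            preds = [u for u in np.flatnonzero(adj[v]) if d[s, u] == d[s, v] - 1]
            sigma[s, v] = sum(sigma[s, u] for u in preds)
    return sigma


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via the pair-dependency identity.

    b_i = sum over unordered pairs {s, t} (s, t != i) of
    sigma_st(i) / sigma_st, with sigma_st(i) = sigma_si * sigma_it when i is
    on a shortest s-t path.
    """
    n = adj.shape[0]
    d = distances(adj)
    sigma = _path_counts(adj, d)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                if d[s, i] + d[i, t] == d[s, t]:
                    out[i] += sigma[s, i] * sigma[i, t] / sigma[s, t]
    return out


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    adj = (rng.random((n, n)) < p).astype(np.uint8)
    adj = np.triu(adj, 1)
    return adj + adj.T
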