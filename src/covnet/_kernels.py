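"""Low-level graph kernels on bitset adjacency matrices.

A graph on ``n`` nodes is stored as an ``(n, ceil(n/64))`` array of uint64
words, one bitmask row per node.  All shortest-path work is level-synchronous
BFS over bitmask frontiers, which keeps the permutation machinery (millions
of 68-node graph evaluations) tractable on one CPU.  Everything here is
deterministic given the seeds passed in; the Maslov–Sneppen rewiring uses
numba's own np.random state, seeded explicitly per call.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "adjacency_to_bits",
    "bits_to_adjacency",
    "bfs_stats",
    "char_path_length",
    "clustering_and_degree",
    "local_efficiency_nodes",
    "betweenness_nodes",
    "rewire_seeded",
    "ensemble_curves",
]

_U0 = np.uint64(0)
_U1 = np.uint64(1)


@njit(cache=True, inline="always")
def _popcount(x):
    x = x - ((x >> np.uint64(1)) & np.uint64(0x5555555555555555))
    x = (x & np.uint64(0x3333333333333333)) + (
        (x >> np.uint64(2)) & np.uint64(0x3333333333333333)
    )
    x = (x + (x >> np.uint64(4))) & np.uint64(0x0F0F0F0F0F0F0F0F)
    return int((x * np.uint64(0x0101010101010101)) >> np.uint64(56))


@njit(cache=True, inline="always")
def _lowbit_index(x):
    # index of least-significant set bit; x must be nonzero
    return _popcount((x & (~x + np.uint64(1))) - np.uint64(1))


@njit(cache=True, inline="always")
def _testbit(bits, i, j):
    return (bits[i, j >> 6] >> np.uint64(j & 63)) & np.uint64(1) != np.uint64(0)


@njit(cache=True, inline="always")
def _setbit(bits, i, j):
    bits[i, j >> 6] |= np.uint64(1) << np.uint64(j & 63)


@njit(cache=True, inline="always")
def _clearbit(bits, i, j):
    bits[i, j >> 6] &= ~(np.uint64(1) << np.uint64(j & 63))


def adjacency_to_bits(adj: np.ndarray) -> np.ndarray:
    """Pack a dense 0/1 symmetric adjacency matrix into bitset rows."""
    adj = np.asarray(adj)
    n = adj.shape[0]
    nwords = (n + 63) // 64
    bits = np.zeros((n, nwords), dtype=np.uint64)
    ii, jj = np.nonzero(adj)
    for i, j in zip(ii, jj):
        bits[i, j >> 6] |= np.uint64(1) << np.uint64(j & 63)
    return bits


def bits_to_adjacency(bits: np.ndarray, n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for w in range(bits.shape[1]):
            word = int(bits[i, w])
            while word:
                low = word & -word
                adj[i, (w << 6) + low.bit_length() - 1] = 1
                word ^= low
    return adj


@njit(cache=True)
def bfs_stats(bits):
    """Per-source BFS aggregates.

    Returns (eff, reach, sumd, comp_root) where for each source ``s``:
    eff[s] is the nodal efficiency mean(1/d(s, j)) over j != s with 1/inf = 0,
    reach[s] the number of reachable other nodes, sumd[s] the sum of finite
    distances, and comp_root[s] the smallest node index in s's component.
    """
    n = bits.shape[0]
    nwords = bits.shape[1]
    eff = np.zeros(n)
    reach = np.zeros(n, np.int64)
    sumd = np.zeros(n, np.int64)
    comp_root = np.zeros(n, np.int64)
    seen = np.zeros(nwords, np.uint64)
    frontier = np.zeros(nwords, np.uint64)
    nxt = np.zeros(nwords, np.uint64)
    for s in range(n):
        for w in range(nwords):
            seen[w] = _U0
        seen[s >> 6] = _U1 << np.uint64(s & 63)
        for w in range(nwords):
            frontier[w] = bits[s, w] & ~seen[w]
        d = 0
        suminv = 0.0
        sd = 0
        rc = 0
        while True:
            c = 0
            for w in range(nwords):
                c += _popcount(frontier[w])
            if c == 0:
                break
            d += 1
            suminv += c / d
            sd += d * c
            rc += c
            for w in range(nwords):
                seen[w] |= frontier[w]
            if rc == n - 1:
                break
            for w in range(nwords):
                nxt[w] = _U0
            for w in range(nwords):
                f = frontier[w]
                while f != _U0:
                    j = (w << 6) + _lowbit_index(f)
                    f &= f - _U1
                    for w2 in range(nwords):
                        nxt[w2] |= bits[j, w2]
            for w in range(nwords):
                frontier[w] = nxt[w] & ~seen[w]
        if n > 1:
            eff[s] = suminv / (n - 1)
        reach[s] = rc
        sumd[s] = sd
        root = s
        for w in range(nwords):
            if seen[w] != _U0:
                root = (w << 6) + _lowbit_index(seen[w])
                break
        comp_root[s] = root
    return eff, reach, sumd, comp_root


@njit(cache=True)
def char_path_length(reach, sumd, comp_root, n):
    """Mean shortest-path distance over ordered pairs in the largest component.

    Returns 0.0 when the largest component has fewer than 2 nodes (caller
    decides whether that is an error).  Ties between equally large components
    are broken toward the component containing the smallest node index.
    """
    best_root = -1
    best_size = 0
    for s in range(n):
        sz = reach[s] + 1
        r = comp_root[s]
        if sz > best_size or (sz == best_size and (best_root == -1 or r < best_root)):
            best_size = sz
            best_root = r
    if best_size < 2:
        return 0.0
    tot = 0
    for s in range(n):
        if comp_root[s] == best_root:
            tot += sumd[s]
    return tot / (best_size * (best_size - 1))


@njit(cache=True)
def clustering_and_degree(bits):
    """Per-node clustering coefficient (0 for degree < 2) and degree."""
    n = bits.shape[0]
    nwords = bits.shape[1]
    clus = np.zeros(n)
    deg = np.zeros(n, np.int64)
    for i in range(n):
        k = 0
        for w in range(nwords):
            k += _popcount(bits[i, w])
        deg[i] = k
        if k < 2:
            continue
        t = 0
        for w in range(nwords):
            f = bits[i, w]
            while f != _U0:
                j = (w << 6) + _lowbit_index(f)
                f &= f - _U1
                for w2 in range(nwords):
                    t += _popcount(bits[i, w2] & bits[j, w2])
        # t counts each triangle at i twice (once per adjacent neighbour pair
        # ordering), so C_i = 2*T_i / (k(k-1)) = t / (k(k-1)).
        clus[i] = t / (k * (k - 1))
    return clus, deg


@njit(cache=True)
def local_efficiency_nodes(bits):
    """Per-node local efficiency: efficiency of the neighbour-induced subgraph."""
    n = bits.shape[0]
    nwords = bits.shape[1]
    eloc = np.zeros(n)
    seen = np.zeros(nwords, np.uint64)
    frontier = np.zeros(nwords, np.uint64)
    nxt = np.zeros(nwords, np.uint64)
    for i in range(n):
        k = 0
        for w in range(nwords):
            k += _popcount(bits[i, w])
        if k < 2:
            continue
        tot = 0.0
        for w0 in range(nwords):
            fi = bits[i, w0]
            while fi != _U0:
                j = (w0 << 6) + _lowbit_index(fi)
                fi &= fi - _U1
                # BFS from j restricted to N(i)
                for w in range(nwords):
                    seen[w] = _U0
                seen[j >> 6] = _U1 << np.uint64(j & 63)
                for w in range(nwords):
                    frontier[w] = bits[j, w] & bits[i, w] & ~seen[w]
                d = 0
                rc = 0
                while True:
                    c = 0
                    for w in range(nwords):
                        c += _popcount(frontier[w])
                    if c == 0:
                        break
                    d += 1
                    tot += c / d
                    rc += c
                    for w in range(nwords):
                        seen[w] |= frontier[w]
                    if rc == k - 1:
                        break
                    for w in range(nwords):
                        nxt[w] = _U0
                    for w in range(nwords):
                        f = frontier[w]
                        while f != _U0:
                            u = (w << 6) + _lowbit_index(f)
                            f &= f - _U1
                            for w2 in range(nwords):
                                nxt[w2] |= bits[u, w2]
                    for w in range(nwords):
                        frontier[w] = nxt[w] & bits[i, w] & ~seen[w]
        eloc[i] = tot / (k * (k - 1))
    return eloc


@njit(cache=True)
def betweenness_nodes(bits):
    """Brandes betweenness centrality, unnormalized, unordered-pair counting."""
    n = bits.shape[0]
    nwords = bits.shape[1]
    bc = np.zeros(n)
    dist = np.empty(n, np.int64)
    sigma = np.empty(n)
    delta = np.empty(n)
    order = np.empty(n, np.int64)
    for s in range(n):
        for v in range(n):
            dist[v] = -1
            sigma[v] = 0.0
            delta[v] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head = 0
        tail = 1
        while head < tail:
            v = order[head]
            head += 1
            dv = dist[v]
            for w in range(nwords):
                f = bits[v, w]
                while f != _U0:
                    u = (w << 6) + _lowbit_index(f)
                    f &= f - _U1
                    if dist[u] < 0:
                        dist[u] = dv + 1
                        order[tail] = u
                        tail += 1
                    if dist[u] == dv + 1:
                        sigma[u] += sigma[v]
        for idx in range(tail - 1, 0, -1):
            u = order[idx]
            coef = (1.0 + delta[u]) / sigma[u]
            du = dist[u]
            for w in range(nwords):
                f = bits[u, w]
                while f != _U0:
                    v = (w << 6) + _lowbit_index(f)
                    f &= f - _U1
                    if dist[v] == du - 1:
                        delta[v] += sigma[v] * coef
            if u != s:
                bc[u] += delta[u]
    for v in range(n):
        bc[v] *= 0.5
    return bc


@njit(cache=True)
def _rewire(bits, eu, ev, n_attempts):
    """Maslov–Sneppen double-edge swaps in place; returns successful swaps."""
    m = eu.shape[0]
    nsucc = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(0, m)
        e2 = np.random.randint(0, m)
        if e1 == e2:
            continue
        a = eu[e1]
        b = ev[e1]
        c = eu[e2]
        d = ev[e2]
        if np.random.randint(0, 2) == 1:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or b == c:
            continue
        if _testbit(bits, a, d) or _testbit(bits, c, b):
            continue
        _clearbit(bits, a, b)
        _clearbit(bits, b, a)
        _clearbit(bits, c, d)
        _clearbit(bits, d, c)
        _setbit(bits, a, d)
        _setbit(bits, d, a)
        _setbit(bits, c, b)
        _setbit(bits, b, c)
        eu[e1] = a
        ev[e1] = d
        eu[e2] = c
        ev[e2] = b
        nsucc += 1
    return nsucc


@njit(cache=True)
def rewire_seeded(bits, eu, ev, n_attempts, seed):
    np.random.seed(seed)
    return _rewire(bits, eu, ev, n_attempts)


@njit(cache=True)
def _ref_add_edge(bits, eu, ev, m, i, j):
    """Add an edge to a reference graph so that deg(i) and deg(j) each grow by 1.

    If (i, j) is absent it is simply added.  If it already exists (the
    reference was rewired), a random existing edge (u, v) disjoint from
    {i, j} with (i, u) and (j, v) absent is replaced by (i, u) and (j, v),
    which yields the same degree increments.  Returns the new edge count
    (unchanged if no valid repair exists, which only occurs for
    near-complete neighbourhoods).
    """
    if not _testbit(bits, i, j):
        _setbit(bits, i, j)
        _setbit(bits, j, i)
        eu[m] = i
        ev[m] = j
        return m + 1
    for _ in range(50):
        e = np.random.randint(0, m)
        u = eu[e]
        v = ev[e]
        if np.random.randint(0, 2) == 1:
            u, v = v, u
        if u == i or u == j or v == i or v == j:
            continue
        if _testbit(bits, i, u) or _testbit(bits, j, v):
            continue
        _clearbit(bits, u, v)
        _clearbit(bits, v, u)
        _setbit(bits, i, u)
        _setbit(bits, u, i)
        _setbit(bits, j, v)
        _setbit(bits, v, j)
        eu[e] = i
        ev[e] = u
        eu[m] = j
        ev[m] = v
        return m + 1
    # deterministic fallback scan
    for e in range(m):
        for o in range(2):
            u = eu[e] if o == 0 else ev[e]
            v = ev[e] if o == 0 else eu[e]
            if u == i or u == j or v == i or v == j:
                continue
            if _testbit(bits, i, u) or _testbit(bits, j, v):
                continue
            _clearbit(bits, u, v)
            _clearbit(bits, v, u)
            _setbit(bits, i, u)
            _setbit(bits, u, i)
            _setbit(bits, j, v)
            _setbit(bits, v, j)
            eu[e] = i
            ev[e] = u
            eu[m] = j
            ev[m] = v
            return m + 1
    return m


@njit(cache=True)
def reference_sweep_check(order_i, order_j, ks, n, swaps_per_edge, seed):
    """Test hook: max |deg_obs - deg_ref| per density for the incremental reference."""
    nwords = (n + 63) // 64
    nd = ks.shape[0]
    out = np.zeros(nd, np.int64)
    bits = np.zeros((n, nwords), np.uint64)
    mmax = ks[nd - 1]
    eu = np.empty(mmax, np.int64)
    ev = np.empty(mmax, np.int64)
    rbits = np.zeros((n, nwords), np.uint64)
    reu = np.empty(mmax, np.int64)
    rev = np.empty(mmax, np.int64)
    rm = 0
    pos = 0
    for t in range(nd):
        k = ks[t]
        kprev = pos
        while pos < k:
            i = order_i[pos]
            j = order_j[pos]
            _setbit(bits, i, j)
            _setbit(bits, j, i)
            eu[pos] = i
            ev[pos] = j
            pos += 1
        np.random.seed((seed + 7919 * t) % 2147483647)
        if t == 0:
            rbits[:, :] = bits
            for e in range(k):
                reu[e] = eu[e]
                rev[e] = ev[e]
            rm = k
            _rewire(rbits, reu[:k], rev[:k], swaps_per_edge * k)
        else:
            for e in range(kprev, k):
                rm = _ref_add_edge(rbits, reu, rev, rm, eu[e], ev[e])
            _rewire(rbits, reu[:rm], rev[:rm], swaps_per_edge * (k - kprev))
        worst = 0
        for v in range(n):
            dobs = 0
            dref = 0
            for w in range(nwords):
                dobs += _popcount(bits[v, w])
                dref += _popcount(rbits[v, w])
            diff = dobs - dref
            if diff < 0:
                diff = -diff
            if diff > worst:
                worst = diff
        out[t] = worst
    return out


@njit(cache=True)
def ensemble_curves(order_i, order_j, ks, n, n_null, swaps_per_edge, base_seed,
                    compute_nodal):
    """Metric curves over a nested density sweep.

    ``order_i``/``order_j`` rank all candidate edges strongest-first; graph t
    consists of the first ``ks[t]`` edges, so the sweep is built incrementally.

    Degree-matched references for the gamma/lambda normalization are also
    maintained incrementally: each reference starts as a fully rewired copy
    of the sparsest graph, and at every subsequent density receives the same
    newly added edges (with degree-preserving repair when an edge is already
    present) followed by ``swaps_per_edge`` double-edge swaps per new edge.
    The degree sequence therefore tracks the observed graph at every density
    while the total randomization effort stays proportional to the final
    edge count.

    Returns
    -------
    raw : (4, nd) array — clustering mean, characteristic path length,
        global efficiency, local efficiency mean per density.
    norm : (2, nd) array — gamma (C/C_rand) and lambda (L/L_rand), zero rows
        if n_null == 0.  Degenerate null means fall back to a ratio of 1
        when the numerator is also degenerate.
    deg_c, eff_c, btw_c : (nd, n) nodal curves (zeros unless compute_nodal).
    """
    nwords = (n + 63) // 64
    nd = ks.shape[0]
    raw = np.zeros((4, nd))
    norm = np.zeros((2, nd))
    deg_c = np.zeros((nd, n))
    eff_c = np.zeros((nd, n))
    btw_c = np.zeros((nd, n))
    bits = np.zeros((n, nwords), np.uint64)
    mmax = ks[nd - 1]
    eu = np.empty(mmax, np.int64)
    ev = np.empty(mmax, np.int64)
    rbits = np.zeros((n_null, n, nwords), np.uint64)
    reu = np.empty((n_null, mmax), np.int64)
    rev = np.empty((n_null, mmax), np.int64)
    rm = np.zeros(n_null, np.int64)
    pos = 0
    for t in range(nd):
        k = ks[t]
        kprev = pos
        while pos < k:
            i = order_i[pos]
            j = order_j[pos]
            _setbit(bits, i, j)
            _setbit(bits, j, i)
            eu[pos] = i
            ev[pos] = j
            pos += 1
        clus, deg = clustering_and_degree(bits)
        eff, reach, sumd, comp_root = bfs_stats(bits)
        cmean = clus.mean()
        lpath = char_path_length(reach, sumd, comp_root, n)
        eglob = eff.mean()
        eloc = local_efficiency_nodes(bits).mean()
        raw[0, t] = cmean
        raw[1, t] = lpath
        raw[2, t] = eglob
        raw[3, t] = eloc
        if n_null > 0:
            csum = 0.0
            lsum = 0.0
            for r in range(n_null):
                np.random.seed((base_seed + 7919 * t + 104729 * r) % 2147483647)
                if t == 0:
                    rbits[r, :, :] = bits
                    for e in range(k):
                        reu[r, e] = eu[e]
                        rev[r, e] = ev[e]
                    rm[r] = k
                    _rewire(rbits[r], reu[r, :k], rev[r, :k], swaps_per_edge * k)
                else:
                    for e in range(kprev, k):
                        rm[r] = _ref_add_edge(
                            rbits[r], reu[r], rev[r], rm[r], eu[e], ev[e]
                        )
                    mr = rm[r]
                    _rewire(
                        rbits[r], reu[r, :mr], rev[r, :mr],
                        swaps_per_edge * (k - kprev),
                    )
                cn, _ = clustering_and_degree(rbits[r])
                effn, reachn, sumdn, rootn = bfs_stats(rbits[r])
                csum += cn.mean()
                lsum += char_path_length(reachn, sumdn, rootn, n)
            cnull = csum / n_null
            lnull = lsum / n_null
            if cnull > 0.0:
                norm[0, t] = cmean / cnull
            else:
                norm[0, t] = 1.0 if cmean == 0.0 else np.nan
            if lnull > 0.0:
                norm[1, t] = lpath / lnull
            else:
                norm[1, t] = 1.0 if lpath == 0.0 else np.nan
        if compute_nodal:
            btw = betweenness_nodes(bits)
            for v in range(n):
                deg_c[t, v] = deg[v]
                eff_c[t, v] = eff[v]
                btw_c[t, v] = btw[v]
    return raw, norm, deg_c, eff_c, btw_c
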