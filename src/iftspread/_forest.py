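"""Priority-queue kernel for the optimum-path forest (numba-compiled).

The forest is the unique fixed point of the lexicographic key

    key(q) = min over paths pi from any seed to q of
             (cost(pi), hops(pi), seed_order(pi), pred(pi))

where cost extends monotonically along arcs (max-arc or additive),
``hops`` is the arc count, ``seed_order`` the index of the originating
seed in the seed list and ``pred`` the flat index of the penultimate
node (-1 for trivial paths).  Because cost never decreases along an arc
and hops strictly increase, the key strictly increases along every path
extension, so a Dijkstra-style scan with this key as priority finalises
each node at its optimum.  The same key is computed by the pure-Python
Bellman-style oracle in :mod:`iftspread.ift`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# key component layout in the heap / best arrays: (cost, hops, seed, pred)


@njit(cache=True, inline="always")
def _less(c1, h1, s1, p1, c2, h2, s2, p2):
    if c1 != c2:
        return c1 < c2
    if h1 != h2:
        return h1 < h2
    if s1 != s2:
        return s1 < s2
    return p1 < p2


@njit(cache=True)
def forest_kernel(values, offs, scales, seed_nodes, additive, handicap):
    """Compute the optimum-path forest.

    Parameters
    ----------
    values : float64 (T, H, W) intensities (already pre-smoothed if requested)
    offs : int64 (k, 3) neighbour offsets (dt, dr, dc)
    scales : float64 (k,) arc-weight multiplier per offset
    seed_nodes : int64 (m,) flat node index per seed entry, in seed order
    additive : bool — additive path cost if true, max-arc otherwise
    handicap : float64 — initial cost at seeds

    Returns
    -------
    best_cost, best_hops, best_seed, best_pred : flat arrays of length N.
    ``best_seed`` is the winning seed-entry index (-1 if unreachable),
    ``best_pred`` the predecessor flat index (-1 at roots).
    """
    T, H, W = values.shape
    N = T * H * W
    n_off = offs.shape[0]
    INF = np.inf
    BIG = np.int64(2**62)

    best_cost = np.full(N, INF, dtype=np.float64)
    best_hops = np.full(N, BIG, dtype=np.int64)
    best_seed = np.full(N, BIG, dtype=np.int64)
    best_pred = np.full(N, BIG, dtype=np.int64)
    done = np.zeros(N, dtype=np.uint8)

    cap = 1024
    hc = np.empty(cap, dtype=np.float64)
    hh = np.empty(cap, dtype=np.int64)
    hs = np.empty(cap, dtype=np.int64)
    hp = np.empty(cap, dtype=np.int64)
    hn = np.empty(cap, dtype=np.int64)
    size = 0

    flat = values.ravel()

    # seed initialisation: earlier entries win ties by construction of the key
    for i in range(seed_nodes.shape[0]):
        n = seed_nodes[i]
        if _less(handicap, 0, i, -1, best_cost[n], best_hops[n], best_seed[n], best_pred[n]):
            best_cost[n] = handicap
            best_hops[n] = 0
            best_seed[n] = i
            best_pred[n] = -1
            # push
            if size == cap:
                cap2 = cap * 2
                nhc = np.empty(cap2, dtype=np.float64)
                nhh = np.empty(cap2, dtype=np.int64)
                nhs = np.empty(cap2, dtype=np.int64)
                nhp = np.empty(cap2, dtype=np.int64)
                nhn = np.empty(cap2, dtype=np.int64)
                nhc[:size] = hc[:size]
                nhh[:size] = hh[:size]
                nhs[:size] = hs[:size]
                nhp[:size] = hp[:size]
                nhn[:size] = hn[:size]
                hc, hh, hs, hp, hn, cap = nhc, nhh, nhs, nhp, nhn, cap2
            j = size
            hc[j] = handicap
            hh[j] = 0
            hs[j] = i
            hp[j] = -1
            hn[j] = n
            size += 1
            while j > 0:
                par = (j - 1) // 2
                if _less(hc[j], hh[j], hs[j], hp[j], hc[par], hh[par], hs[par], hp[par]):
                    hc[j], hc[par] = hc[par], hc[j]
                    hh[j], hh[par] = hh[par], hh[j]
                    hs[j], hs[par] = hs[par], hs[j]
                    hp[j], hp[par] = hp[par], hp[j]
                    hn[j], hn[par] = hn[par], hn[j]
                    j = par
                else:
                    break

    HW = H * W
    while size > 0:
        # pop min
        pc = hc[0]
        ph = hh[0]
        ps = hs[0]
        pp = hp[0]
        pn = hn[0]
        size -= 1
        if size > 0:
            hc[0] = hc[size]
            hh[0] = hh[size]
            hs[0] = hs[size]
            hp[0] = hp[size]
            hn[0] = hn[size]
            j = 0
            while True:
                l = 2 * j + 1
                r = l + 1
                m = j
                if l < size and _less(hc[l], hh[l], hs[l], hp[l], hc[m], hh[m], hs[m], hp[m]):
                    m = l
                if r < size and _less(hc[r], hh[r], hs[r], hp[r], hc[m], hh[m], hs[m], hp[m]):
                    m = r
                if m == j:
                    break
                hc[j], hc[m] = hc[m], hc[j]
                hh[j], hh[m] = hh[m], hh[j]
                hs[j], hs[m] = hs[m], hs[j]
                hp[j], hp[m] = hp[m], hp[j]
                hn[j], hn[m] = hn[m], hn[j]
                j = m

        if done[pn]:
            continue
        # stale entry: a better key was pushed later
        if pc != best_cost[pn] or ph != best_hops[pn] or ps != best_seed[pn] or pp != best_pred[pn]:
            continue
        done[pn] = 1

        t = pn // HW
        rem = pn - t * HW
        r = rem // W
        c = rem - r * W
        ival = flat[pn]

        for k in range(n_off):
            qt = t + offs[k, 0]
            qr = r + offs[k, 1]
            qc = c + offs[k, 2]
            if qt < 0 or qt >= T or qr < 0 or qr >= H or qc < 0 or qc >= W:
                continue
            qn = qt * HW + qr * W + qc
            if done[qn]:
                continue
            w = abs(ival - flat[qn]) * scales[k]
            if additive:
                ncost = pc + w
            else:
                ncost = pc if pc > w else w
            nhops = ph + 1
            if _less(ncost, nhops, ps, pn, best_cost[qn], best_hops[qn], best_seed[qn], best_pred[qn]):
                best_cost[qn] = ncost
                best_hops[qn] = nhops
                best_seed[qn] = ps
                best_pred[qn] = pn
                if size == cap:
                    cap2 = cap * 2
                    nhc = np.empty(cap2, dtype=np.float64)
                    nhh = np.empty(cap2, dtype=np.int64)
                    nhs = np.empty(cap2, dtype=np.int64)
                    nhp = np.empty(cap2, dtype=np.int64)
                    nhn = np.empty(cap2, dtype=np.int64)
                    nhc[:size] = hc[:size]
                    nhh[:size] = hh[:size]
                    nhs[:size] = hs[:size]
                    nhp[:size] = hp[:size]
                    nhn[:size] = hn[:size]
                    hc, hh, hs, hp, hn, cap = nhc, nhh, nhs, nhp, nhn, cap2
                j = size
                hc[j] = ncost
                hh[j] = nhops
                hs[j] = ps
                hp[j] = pn
                hn[j] = qn
                size += 1
                while j > 0:
                    par = (j - 1) // 2
                    if _less(hc[j], hh[j], hs[j], hp[j], hc[par], hh[par], hs[par], hp[par]):
                        hc[j], hc[par] = hc[par], hc[j]
                        hh[j], hh[par] = hh[par], hh[j]
                        hs[j], hs[par] = hs[par], hs[j]
                        hp[j], hp[par] = hp[par], hp[j]
                        hn[j], hn[par] = hn[par], hn[j]
                        j = par
                    else:
                        break

    # sentinel cleanup for unreachable nodes
    for n in range(N):
        if best_seed[n] == BIG:
            best_seed[n] = -1
            best_pred[n] = -1
            best_hops[n] = -1
    return best_cost, best_hops, best_seed, best_pred
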