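"""Image foresting transform: seeded minimum-cost path labelling.

`run_ift` labels every image element of a (possibly multi-frame) grid
with the label of the seed reaching it along the cheapest path, under a
max-arc or additive path cost on absolute intensity differences.
`brute_force_ift` is an independent fixed-point (Bellman-style)
implementation of the same contract, intended as a test oracle on small
grids.

Determinism.  When several seeds reach a node at equal cost the winner
is defined by the lexicographic key (cost, hop count, seed-entry order,
predecessor flat index).  The key is a property of the graph, not of
the traversal order, so both implementations — and any re-run — produce
bit-identical forests.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (
    AdjacencySpec,
    CostModel,
    IFTResult,
    ImageGrid,
    SeedSet,
    SeedValidationError,
)

__all__ = ["arc_weight", "run_ift", "brute_force_ift"]

_BRUTE_FORCE_NODE_LIMIT = 10_000


def _smoothed_values(grid: ImageGrid, model: CostModel) -> np.ndarray:
    """Intensities used for arc weighting: per-frame Gaussian smoothing
    with ``model.smoothing_sigma`` (0 = raw values)."""
    if model.smoothing_sigma == 0:
        return grid.values
    return ndimage.gaussian_filter(
        grid.values, sigma=(0.0, model.smoothing_sigma, model.smoothing_sigma)
    )


def arc_weight(
    grid: ImageGrid,
    p: tuple[int, int, int],
    q: tuple[int, int, int],
    model: CostModel = CostModel(),
    adj: AdjacencySpec = AdjacencySpec(),
) -> float:
    """Weight of the arc between adjacent nodes ``p`` and ``q``.

    ``|I(p) - I(q)|``, multiplied by ``adj.temporal_weight_scale`` for
    arcs that cross frames.  Symmetric; zero iff the (smoothed)
    intensities are equal, up to the temporal scaling.  Raises
    ``ValueError`` if the pair is not adjacent under ``adj``.
    """
    dt, dr, dc = (int(q[i]) - int(p[i]) for i in range(3))
    offs, scales = adj.offsets(n_frames=grid.n_frames)
    match = np.flatnonzero((offs[:, 0] == dt) & (offs[:, 1] == dr) & (offs[:, 2] == dc))
    if match.size == 0:
        raise ValueError(f"nodes {p} and {q} are not adjacent under {adj}")
    vals = _smoothed_values(grid, model)
    return float(abs(vals[p] - vals[q]) * scales[match[0]])


def _prepare(grid: ImageGrid, seeds: SeedSet, adj: AdjacencySpec, model: CostModel):
    # forest level: bounds/conflict checks only; background+cell presence
    # is the segmentation layer's contract
    seeds.validate(grid, require_labels=False)
    T, H, W = grid.shape
    seed_nodes = (
        seeds.entries[:, 0] * (H * W) + seeds.entries[:, 1] * W + seeds.entries[:, 2]
    ).astype(np.int64)
    offs, scales = adj.offsets(n_frames=T)
    vals = np.ascontiguousarray(_smoothed_values(grid, model))
    return vals, offs, scales, seed_nodes


def _as_result(grid, seeds, cost, hops, seed_idx, pred) -> IFTResult:
    if np.any(seed_idx < 0):
        n_bad = int(np.sum(seed_idx < 0))
        raise ValueError(
            f"{n_bad} nodes are unreachable from the seeds (disconnected graph; "
            "with temporal=False every frame needs its own seeds)"
        )
    shape = grid.shape
    seed_labels = seeds.entries[:, 3]
    T, H, W = shape
    seed_nodes = seeds.entries[:, 0] * (H * W) + seeds.entries[:, 1] * W + seeds.entries[:, 2]
    return IFTResult(
        label_map=seed_labels[seed_idx].reshape(shape),
        cost_map=cost.reshape(shape),
        pred_map=pred.reshape(shape),
        root_map=seed_nodes[seed_idx].reshape(shape),
        hop_map=hops.astype(np.int64).reshape(shape),
    )


def run_ift(
    grid: ImageGrid,
    seeds: SeedSet,
    adj: AdjacencySpec = AdjacencySpec(),
    model: CostModel = CostModel(),
) -> IFTResult:
    """Compute the optimum-path forest with a priority-queue scan.

    Near-linear in node count (times the log of the queue size);
    deterministic given inputs.  Raises ``SeedValidationError`` for
    invalid seed sets and ``ValueError`` if some node is unreachable.
    """
    from ._forest import forest_kernel  # deferred: numba compilation on first use

    vals, offs, scales, seed_nodes = _prepare(grid, seeds, adj, model)
    cost, hops, seed_idx, pred = forest_kernel(
        vals,
        offs,
        scales,
        seed_nodes,
        model.path_rule == "additive",
        float(model.seed_handicap),
    )
    return _as_result(grid, seeds, cost, hops, seed_idx, pred)


def brute_force_ift(
    grid: ImageGrid,
    seeds: SeedSet,
    adj: AdjacencySpec = AdjacencySpec(),
    model: CostModel = CostModel(),
) -> IFTResult:
    """Fixed-point relaxation oracle for :func:`run_ift` (small grids only).

    Two order-independent Bellman-style fixed points, valid for both
    monotone path-cost rules:

    1. scalar costs — relax ``cost(q) <- extend(cost(p), w(p, q))`` over
       every arc until nothing changes, yielding the minimum path cost
       per node;
    2. tie resolution — restricted to the *tight* arcs (those realising
       ``extend(cost(p), w) == cost(q)``, i.e. the arcs cost-optimal
       paths are made of), relax the lexicographic (hops, seed-order,
       pred) key to its fixed point.

    The result is the unique forest of the documented tie rule, hence
    identical to `run_ift`'s output on any instance.
    """
    vals, offs, scales, seed_nodes = _prepare(grid, seeds, adj, model)
    T, H, W = grid.shape
    N = T * H * W
    if N > _BRUTE_FORCE_NODE_LIMIT:
        raise ValueError(f"brute-force oracle limited to {_BRUTE_FORCE_NODE_LIMIT} nodes, got {N}")
    additive = model.path_rule == "additive"
    handicap = float(model.seed_handicap)
    flat = vals.ravel()
    HW = H * W

    def neighbours(pn: int):
        t, rem = divmod(pn, HW)
        r, c = divmod(rem, W)
        for k in range(offs.shape[0]):
            qt, qr, qc = t + offs[k, 0], r + offs[k, 1], c + offs[k, 2]
            if 0 <= qt < T and 0 <= qr < H and 0 <= qc < W:
                qn = int(qt * HW + qr * W + qc)
                yield qn, abs(flat[pn] - flat[qn]) * float(scales[k])

    # stage 1: minimum path cost (order-independent for monotone rules)
    cost = np.full(N, np.inf)
    for n in seed_nodes:
        cost[n] = min(cost[n], handicap)
    changed = True
    while changed:
        changed = False
        for pn in range(N):
            if not np.isfinite(cost[pn]):
                continue
            for qn, w in neighbours(pn):
                ncost = cost[pn] + w if additive else max(cost[pn], w)
                if ncost < cost[qn]:
                    cost[qn] = ncost
                    changed = True

    # stage 2: (hops, seed, pred) fixed point over tight arcs only
    BIG = 2**62
    key2 = [(BIG, BIG, BIG)] * N
    for i, n in enumerate(seed_nodes):
        if cost[n] == handicap:
            cand = (0, i, -1)
            if cand < key2[n]:
                key2[int(n)] = cand
    changed = True
    while changed:
        changed = False
        for pn in range(N):
            if key2[pn][0] == BIG:
                continue
            ph, ps, _ = key2[pn]
            for qn, w in neighbours(pn):
                ncost = cost[pn] + w if additive else max(cost[pn], w)
                if ncost != cost[qn]:
                    continue  # not a tight arc
                cand = (ph + 1, ps, pn)
                if cand < key2[qn]:
                    key2[qn] = cand
                    changed = True

    hops = np.array([k[0] if k[0] != BIG else -1 for k in key2], dtype=np.int64)
    seed_idx = np.array([k[1] if k[1] != BIG else -1 for k in key2], dtype=np.int64)
    pred = np.array([k[2] if k[2] != BIG else -1 for k in key2], dtype=np.int64)
    return _as_result(grid, seeds, cost, hops, seed_idx, pred)
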