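"""Shared helpers for forest tests: random instances and invariant checks."""

from __future__ import annotations

import numpy as np

from iftspread import AdjacencySpec, CostModel, ImageGrid, SeedSet
from iftspread.core import IFTResult


def random_instance(rng: np.random.Generator, max_side: int = 6):
    """A random single-frame grid (integer intensities 0-9) with 2-4
    distinct-coordinate seeds whose labels include background 0."""
    H = int(rng.integers(2, max_side + 1))
    W = int(rng.integers(2, max_side + 1))
    grid = ImageGrid(rng.integers(0, 10, (1, H, W)).astype(float))
    k = int(rng.integers(2, 5))
    coords: set[tuple[int, int]] = set()
    while len(coords) < k:
        coords.add((int(rng.integers(0, H)), int(rng.integers(0, W))))
    labels = list(range(k))  # always contains background 0 and a cell
    rng.shuffle(labels)
    entries = [(0, r, c, labels[i]) for i, (r, c) in enumerate(sorted(coords))]
    return grid, SeedSet.from_entries(entries)


def results_identical(a: IFTResult, b: IFTResult) -> bool:
    return (
        np.array_equal(a.label_map, b.label_map)
        and np.array_equal(a.cost_map, b.cost_map)
        and np.array_equal(a.pred_map, b.pred_map)
        and np.array_equal(a.root_map, b.root_map)
        and np.array_equal(a.hop_map, b.hop_map)
    )


def check_forest_invariants(
    grid: ImageGrid,
    seeds: SeedSet,
    result: IFTResult,
    adj: AdjacencySpec,
    model: CostModel,
) -> None:
    """Assert the structural optimum-path-forest contract on a result."""
    T, H, W = grid.shape
    labels = result.label_map.ravel()
    cost = result.cost_map.ravel()
    pred = result.pred_map.ravel()
    root = result.root_map.ravel()

    # full labelling drawn from the seeds' labels
    assert set(np.unique(labels)) <= set(int(l) for l in seeds.labels)

    # seed fidelity
    seed_nodes = seeds.entries[:, 0] * H * W + seeds.entries[:, 1] * W + seeds.entries[:, 2]
    for (t, r, c, lab), n in zip(seeds.entries, seed_nodes):
        assert labels[n] == lab, f"seed at ({t},{r},{c}) lost its label"
        assert cost[n] == model.seed_handicap

    # predecessor paths are acyclic and end at the stored root, which is a seed
    seed_node_set = set(int(n) for n in seed_nodes)
    N = T * H * W
    for n in range(N):
        seen = set()
        cur = n
        while pred[cur] != -1:
            assert cur not in seen, f"predecessor cycle through node {cur}"
            seen.add(cur)
            cur = int(pred[cur])
        assert cur == root[n]
        assert cur in seed_node_set

    # Bellman optimality at every arc
    offs, scales = adj.offsets(n_frames=T)
    vals = grid.values.ravel()
    additive = model.path_rule == "additive"
    for n in range(N):
        t, rem = divmod(n, H * W)
        r, c = divmod(rem, W)
        for k in range(offs.shape[0]):
            qt, qr, qc = t + offs[k, 0], r + offs[k, 1], c + offs[k, 2]
            if not (0 <= qt < T and 0 <= qr < H and 0 <= qc < W):
                continue
            q = int(qt * H * W + qr * W + qc)
            w = abs(vals[n] - vals[q]) * scales[k]
            ext = cost[n] + w if additive else max(cost[n], w)
            assert cost[q] <= ext + 1e-12, f"Bellman violated on arc {n}->{q}"
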