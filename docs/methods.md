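# Methods

## The optimum-path forest model

A 2D+t stack is a graph G = (V, A): nodes are the image elements of all
frames, arcs connect in-plane neighbours (4-connected by default,
8-connected optional) and, when temporal adjacency is enabled (default),
the same pixel in frames t±1. Arc weights are
w(p, q) = |I(p) − I(q)| · s, with s = 1 for in-plane arcs and
s = `temporal_weight_scale` (default 1.0, ≥ 0) for cross-frame arcs; I
may first be smoothed per frame with a Gaussian of
`smoothing_sigma` pixels (default 0, i.e. raw intensities). Intensities
are cast to double precision on input regardless of TIFF bit depth.

Seeds are user-supplied nodes with fixed labels: 0 for background, one
unique positive integer per cell, possibly several seeds per label and
in several slices. Path cost extends monotonically along arcs under one
of two rules:

- **max-arc** (default): cost(π·⟨p,q⟩) = max(cost(π), w(p,q)). This is
  the canonical choice for object delineation: the optimal cost between
  two nodes is the lowest intensity "barrier" separating them, so a
  bright footprint on a dark background is carved out along its contour
  regardless of gradual internal intensity ramps.
- **additive**: cost(π·⟨p,q⟩) = cost(π) + w(p,q).

Trivial paths cost `seed_handicap` (default 0) at seeds and +∞
elsewhere. Every node receives the label, predecessor and root of the
seed whose path reaches it at minimum cost; the resulting predecessor
map is a spanning forest rooted at the seeds.

### Determinism and tie-breaking

On plateaus (uniform regions, integer-valued images) many seeds reach a
node at the same cost, and the partition would otherwise depend on queue
implementation details. The forest is therefore defined as the per-node
minimum of the lexicographic key

    (path cost, hop count, seed-entry order, predecessor flat index)

over all seed paths. Cost never decreases and hops strictly increase
along an arc, so the key strictly increases along every path extension;
a binary-heap Dijkstra scan with this key finalises each node at its
optimum (the kernel is numba-compiled; runtime is near-linear in node
count times the log of queue size — a 256×256×60 volume solves in a few
seconds on one CPU). Because the key is a property of the graph rather
than of a traversal, an independent Bellman-style oracle
(`brute_force_ift`, for grids up to 10⁴ nodes) reproduces the forest
bit-for-bit: it first iterates the scalar-cost relaxation to its fixed
point, then resolves (hops, seed, pred) by a second fixed point
restricted to the *tight* arcs — those with extend(cost(p), w) =
cost(q). The two-stage form matters: a single-pass lexicographic
relaxation can latch onto keys produced by non-cost-optimal prefixes
that the final forest does not contain, whereas both stages above are
order-independent fixed points of monotone operators. The test suite
asserts map-for-map equality between the two implementations on
hundreds of random instances under both cost rules.

Consequences used by the tests: relabelling seeds by a bijection
permutes the label map identically (the key uses seed order, not label
values); adding a seed can only lower costs; every seed keeps its own
label whenever `seed_handicap` = 0, since its trivial path (0 hops)
lexicographically beats any competitor.

## Segmentation modes

- **volume3d** (default): one forest over the full (T, H, W) graph.
  Seeds placed in any slice classify the whole recording at once;
  temporal arcs carry labels across frames through the cell's own
  footprint, whose plateau intensity makes consecutive-frame arcs cheap
  relative to the cell/background contrast.
- **per_frame_propagate**: frame 0 is segmented from its own seeds
  (cells and background required in frame 0); each later frame is
  segmented independently with seeds derived from the previous result —
  every label's region eroded by a disk of
  `propagation_erosion_radius` pixels (default 2, guarding against
  seeds leaking across a moving boundary), falling back to the region's
  deepest interior point (Euclidean distance-transform maximum) when
  erosion empties it. A label that vanishes from a frame is dropped
  from subsequent frames with a warning. This mode suits long drifting
  acquisitions where temporal arcs are unreliable.

Both modes are deterministic; a re-run on identical inputs is
bit-identical, and every run carries a provenance record (configuration,
SHA-256 of the seed entries, software version). Cells touching the
image border are kept — TIRF footprints often sit near the field edge.

## Quantification

Per frame, a cell's area in pixels is its label's pixel count;
area_µm² = area_px × pixel area. Background plus cell areas always sum
to H×W per frame. Labels absent from a frame get explicit zero rows.
The CSV dialect is fixed (header `cell_label,frame,time_s,area_px,
area_um2`, LF endings, '.' decimals, rows sorted by cell then frame,
floats in shortest round-trip form) so write→read→write is
byte-identical.

Cohort curves report, per frame, n, mean area, and s.e.m. computed with
the n−1 sample standard deviation; s.e.m. is flagged undefined (NaN)
when n < 2. Cells contribute only to frames where they are present and
the per-frame n makes attrition visible. Alignment default is the first
acquisition frame = t 0 — recordings start at cell landing — with
optional per-cell frame offsets for other experimental designs. Group
comparison uses the pooled-variance two-sample Student's t
(df = n_a + n_b − 2, two-tailed); zero pooled variance with equal means
returns (t = 0, p = 1), with unequal means (±∞, 0) as a flagged
degenerate outcome. The implementation is closed-form;
`scipy.stats.ttest_ind` appears in tests only as an independent
cross-check.

Blot loading normalisation divides each lane's actin by the reference
lane's actin (reference = 1 exactly) and each antibody signal by its
lane's normalised actin; it is invariant to globally rescaling the actin
channel. R/R₀ normalisation divides the pointwise ratio of two traces
by its mean over a baseline window at the trace start, making the
baseline mean exactly 1 and the output invariant to rescaling either
channel; an optional linear detrend (line fitted to the baseline window,
subtracted before renormalising) is available but off by default, since
slope-correction conventions vary between labs.

## The phantom generator

Each simulated cell has a logistic area law A(t) = A_max /
(1 + exp(−k(t − t₀))) and a star-shaped footprint r(θ) =
r₀(t)·(1 + Σₘ aₘ cos(mθ + φₘ)), m = 2…5. r₀ is chosen so the enclosed
area is *exactly* A(t) — the ripple term integrates to
π r₀²(1 + Σ aₘ²/2) — so analytic truth areas need no correction; pixel
counts differ from A(t) only by boundary discretisation, bounded by the
perimeter-to-area ratio (asserted in tests). Frames are background mean
+ per-cell plateau intensity inside the footprint, then optional Poisson
resampling and additive Gaussian noise; truth labels and areas are
recorded pre-noise. Identical parameters and seed give bit-identical
output.

Defaults emulate a TIRF spreading assay: 256×256 px at 0.5 µm/px
(a 128 µm field under a high-NA 60× objective), 60 frames at 5 s,
background 100, per-cell plateau intensities uniform in [300, 800]
(the cell-to-cell brightness spread that defeats global thresholds),
Gaussian σ = 30 plus Poisson shot noise, 5 cells, A_max ∈ [300, 500] µm²
(spread fibroblast footprints), k = 0.015 s⁻¹ and t₀ ∈ [75, 125] s so a
cell goes from ~18% to ~95% of its plateau within the 5-minute
recording, boundary ripple amplitude 0.1. `default_seed_annotation`
stands in for the user's clicks: a few interior points of each cell in
its first visible frame plus background points ≥ 8 px from every cell's
footprint at any time.

What the phantom does not emulate — PSF blur (boundaries are
pixel-sharp), photobleaching, migration, touching cells, illumination
gradients — bounds what passing tests show: they validate the
algorithmic pipeline (optimality of the forest, correct counting,
correct statistics), not robustness to blurred or overlapping
real-world footprints, where seed placement and pre-smoothing choices
will matter more.

## Problem sizes and numerical notes

The full test suite and the acceptance script run the default
256×256×60 phantom (≈3.9 M nodes) and a 20-cell variant end-to-end;
random-instance oracle comparisons use grids ≤ 6×6 where the brute-force
fixed point is fast. Float arc weights are compared exactly in the
tight-arc test because both implementations compute them with the same
left-associated operations; the monotonicity of x ↦ x + w and
x ↦ max(x, w) holds in IEEE arithmetic, so prefix-optimal relaxation is
exact in floats too. Logistic fits use least squares initialised from
the curve itself (plateau = max, midpoint = time of half-plateau,
k = 4/time-span). Degenerate inputs are defined rather than accidental:
empty seed sets, out-of-bounds or conflicting seeds and unreachable
nodes (e.g. temporal arcs disabled with seeds in one frame only) raise
errors naming the offending entry; a 2-D array is promoted to a T = 1
volume; erosion radius 0 propagates seeds verbatim.

## Known limitations

- Seeds come from files; there is no interactive clicking or automatic
  cell detection.
- Two path-cost rules only; no user-supplied cost plug-ins, no
  incremental seed editing (differential recomputation), no GPU path.
- The per-frame tracker assumes overlap between a cell's positions in
  consecutive frames (true for spreading, not for fast migration).
- Calibration is never read from TIFF metadata; supplying wrong pixel
  size or frame interval rescales areas and times silently.
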