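"""Whole-stack segmentation: apply the forest transform to a time-lapse.

Two modes are supported.  ``volume3d`` (default) treats the whole
(T, H, W) stack as one graph with temporal arcs, so seeds placed in one
or several slices classify every frame at once.  ``per_frame_propagate``
segments frame 0 from its seeds and then tracks each label forward by
eroding the previous frame's regions into seeds for the next frame —
useful for long acquisitions where drift makes temporal arcs unreliable.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from . import __version__ as _pkg_version
from .core import AdjacencySpec, CostModel, ImageGrid, IFTResult, SeedSet
from .ift import run_ift

__all__ = [
    "SegmentationConfig",
    "SegmentationVolume",
    "SeedValidationReport",
    "segment_volume",
    "propagate_seeds",
    "validate_seeds",
    "dice_scores",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation strategy and its graph/cost parameters."""

    mode: str = "volume3d"
    adjacency: AdjacencySpec = field(default_factory=AdjacencySpec)
    cost: CostModel = field(default_factory=CostModel)
    propagation_erosion_radius: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("volume3d", "per_frame_propagate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.propagation_erosion_radius < 0:
            raise ValueError("propagation_erosion_radius must be >= 0")


@dataclass(frozen=True)
class SegmentationVolume:
    """Label per (t, row, col) plus provenance of how it was produced."""

    labels: np.ndarray
    provenance: dict

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def cell_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]


@dataclass(frozen=True)
class SeedValidationReport:
    """Outcome of checking a seed set against a grid; ``ok`` iff no issues."""

    issues: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "seed set valid"
        return "\n".join(self.issues)


def validate_seeds(grid: ImageGrid, seeds: SeedSet) -> SeedValidationReport:
    """Report out-of-bounds, conflicting, or missing seeds (never raises)."""
    return SeedValidationReport(tuple(seeds.issues(grid)))


def _seed_digest(seeds: SeedSet) -> str:
    return hashlib.sha256(np.ascontiguousarray(seeds.entries).tobytes()).hexdigest()


def _provenance(grid: ImageGrid, seeds: SeedSet, config: SegmentationConfig) -> dict:
    return {
        "software": f"iftspread {_pkg_version}",
        "grid_shape": list(grid.shape),
        "spacing": list(grid.spacing),
        "seed_digest": _seed_digest(seeds),
        "n_seeds": len(seeds),
        "mode": config.mode,
        "in_plane": config.adjacency.in_plane,
        "temporal": config.adjacency.temporal,
        "temporal_weight_scale": config.adjacency.temporal_weight_scale,
        "path_rule": config.cost.path_rule,
        "smoothing_sigma": config.cost.smoothing_sigma,
        "seed_handicap": config.cost.seed_handicap,
        "propagation_erosion_radius": config.propagation_erosion_radius,
    }


def propagate_seeds(prev_labels: np.ndarray, radius: int, frame: int = 0) -> SeedSet:
    """Derive next-frame seeds from a segmented frame.

    Each label's region (background included) is eroded by a disk of
    ``radius`` pixels; the surviving pixels become that label's seeds.
    If erosion empties a region, its single deepest interior point (the
    maximum of the Euclidean distance transform) is kept so the label
    survives.  ``radius`` 0 returns the previous labelling verbatim.
    """
    prev_labels = np.asarray(prev_labels)
    if prev_labels.ndim != 2:
        raise ValueError("prev_labels must be a single (H, W) frame")
    entries = []
    selem = disk(radius) if radius > 0 else None
    for lab in np.unique(prev_labels):
        mask = prev_labels == lab
        if selem is not None:
            eroded = ndimage.binary_erosion(mask, structure=selem, border_value=True)
        else:
            eroded = mask
        if not eroded.any():
            # region thinner than the erosion radius: keep its deepest point
            dist = ndimage.distance_transform_edt(mask)
            r, c = np.unravel_index(int(np.argmax(dist)), mask.shape)
            eroded = np.zeros_like(mask)
            eroded[r, c] = True
        rr, cc = np.nonzero(eroded)
        entries.append(
            np.column_stack(
                [np.full(rr.size, frame), rr, cc, np.full(rr.size, lab)]
            )
        )
    return SeedSet(np.concatenate(entries, axis=0))


def _frame_grid(grid: ImageGrid, t: int) -> ImageGrid:
    return ImageGrid(grid.values[t : t + 1], spacing=grid.spacing)


def segment_volume(
    grid: ImageGrid, seeds: SeedSet, config: SegmentationConfig = SegmentationConfig()
) -> SegmentationVolume:
    """Segment a stack into labelled cells and background.

    In ``volume3d`` mode a single forest computation runs over the full
    spatio-temporal graph.  In ``per_frame_propagate`` mode frame 0 is
    segmented from the frame-0 seeds and each later frame from seeds
    eroded out of the previous frame's result; a label that vanishes is
    dropped from subsequent frames with a warning.
    """
    seeds.validate(grid)
    prov = _provenance(grid, seeds, config)
    T = grid.n_frames

    if config.mode == "volume3d" or T == 1:
        res = run_ift(grid, seeds, config.adjacency, config.cost)
        return SegmentationVolume(labels=res.label_map, provenance=prov)

    # per-frame propagation
    frame0 = seeds.entries[seeds.entries[:, 0] == 0]
    if frame0.size == 0 or not np.any(frame0[:, 3] > 0):
        raise ValueError("per_frame_propagate requires cell seeds in frame 0")
    if not np.any(frame0[:, 3] == 0):
        raise ValueError("per_frame_propagate requires background seeds in frame 0")
    adj2d = AdjacencySpec(
        in_plane=config.adjacency.in_plane,
        temporal=False,
        temporal_weight_scale=config.adjacency.temporal_weight_scale,
    )
    labels = np.empty(grid.shape, dtype=np.int64)
    cur_seeds = SeedSet(frame0)
    expected = set(int(l) for l in cur_seeds.labels)
    for t in range(T):
        res = run_ift(_frame_grid(grid, t), cur_seeds, adj2d, config.cost)
        frame_labels = res.label_map[0]
        present = set(int(l) for l in np.unique(frame_labels))
        for lost in sorted(expected - present):
            log.warning("label %d vanished at frame %d; dropped from later frames", lost, t)
        expected &= present
        labels[t] = frame_labels
        if t + 1 < T:
            cur_seeds = propagate_seeds(frame_labels, config.propagation_erosion_radius)
    return SegmentationVolume(labels=labels, provenance=prov)


def dice_scores(seg_labels: np.ndarray, truth_labels: np.ndarray) -> "pandas.DataFrame":
    """Per-cell, per-frame Dice overlap 2|A∩B| / (|A|+|B|) between a
    segmentation and a reference labelling of the same shape.

    Frames where a cell is absent from both volumes are skipped; absent
    from exactly one scores 0.
    """
    import pandas as pd

    seg_labels = np.asarray(seg_labels)
    truth_labels = np.asarray(truth_labels)
    if seg_labels.shape != truth_labels.shape:
        raise ValueError("shape mismatch between segmentation and reference")
    labs = np.unique(truth_labels)
    labs = labs[labs > 0]
    rows = []
    for t in range(truth_labels.shape[0]):
        seg_t, tru_t = seg_labels[t], truth_labels[t]
        for lab in labs:
            a = seg_t == lab
            b = tru_t == lab
            na, nb = int(a.sum()), int(b.sum())
            if na == 0 and nb == 0:
                continue
            dice = 2.0 * int((a & b).sum()) / (na + nb)
            rows.append((int(lab), t, dice))
    return pd.DataFrame(rows, columns=["cell_label", "frame", "dice"])
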