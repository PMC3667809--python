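"""Core graph types for minimum-cost path-forest segmentation.

A fluorescence time-lapse stack is interpreted as a graph whose nodes are
the image elements (pixels of every frame) and whose arcs connect spatially
and, optionally, temporally adjacent elements.  User-placed *seeds* carry
integer labels (0 = background, >=1 = individual cells); segmentation
assigns every node the label of the seed that reaches it along the
minimum-cost path (the image foresting transform, IFT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "AdjacencySpec",
    "SeedSet",
    "CostModel",
    "IFTResult",
    "SeedValidationError",
]


class SeedValidationError(ValueError):
    """Raised when a seed set violates its contract for a given grid."""


@dataclass(frozen=True)
class ImageGrid:
    """An intensity volume of shape (T frames, H rows, W cols).

    Parameters
    ----------
    values
        Non-negative finite intensities, any numeric dtype (cast to
        float64).  A 2-D array is promoted to a single-frame volume.
    spacing
        ``(frame_interval_s, pixel_height_um, pixel_width_um)``; all
        strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (5.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[np.newaxis, :, :]
        if arr.ndim != 3:
            raise ValueError(f"expected a (T, H, W) volume, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("all grid dimensions must be >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("grid intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def frame_interval_s(self) -> float:
        return self.spacing[0]

    @property
    def pixel_area_um2(self) -> float:
        return self.spacing[1] * self.spacing[2]

    @property
    def n_nodes(self) -> int:
        return int(self.values.size)

    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, first frame at t = 0 s."""
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class AdjacencySpec:
    """Which image elements are connected, and how cross-frame arcs scale.

    ``in_plane`` is 4- or 8-connectivity within a frame; ``temporal``
    links each pixel to the same pixel in the previous/next frame;
    ``temporal_weight_scale`` multiplies the weight of cross-frame arcs
    (0 makes temporal arcs free, large values discourage them).
    """

    in_plane: int = 4
    temporal: bool = True
    temporal_weight_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.in_plane not in (4, 8):
            raise ValueError(f"in_plane connectivity must be 4 or 8, got {self.in_plane}")
        if self.temporal_weight_scale < 0:
            raise ValueError("temporal_weight_scale must be >= 0")

    def offsets(self, n_frames: int = 2) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour offsets as ``(k, 3) int array`` of (dt, dr, dc) and a
        matching ``(k,) float array`` of weight multipliers.

        Temporal offsets are omitted when ``temporal`` is false or the
        volume has a single frame.
        """
        offs = [(0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
        if self.in_plane == 8:
            offs += [(0, -1, -1), (0, -1, 1), (0, 1, -1), (0, 1, 1)]
        scales = [1.0] * len(offs)
        if self.temporal and n_frames > 1:
            offs += [(-1, 0, 0), (1, 0, 0)]
            scales += [self.temporal_weight_scale] * 2
        return np.asarray(offs, dtype=np.int64), np.asarray(scales, dtype=np.float64)


@dataclass(frozen=True)
class SeedSet:
    """Labelled seed coordinates: rows of ``(t, row, col, label)``.

    Label 0 is reserved for background; each positive label denotes one
    cell.  Seed order matters: it is the third component of the
    deterministic tie-breaking key, so earlier seeds win exact ties.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(f"seed entries must be (k, 4) of (t, row, col, label), got {arr.shape}")
        if arr.shape[0] == 0:
            raise SeedValidationError("seed set is empty")
        if np.any(arr[:, 3] < 0):
            bad = int(np.argmax(arr[:, 3] < 0))
            raise SeedValidationError(f"seed entry {bad} has negative label {arr[bad, 3]}")
        object.__setattr__(self, "entries", arr)

    @classmethod
    def from_entries(cls, entries: Iterable[Sequence[int]]) -> "SeedSet":
        return cls(np.asarray(list(entries), dtype=np.int64).reshape(-1, 4))

    @property
    def labels(self) -> np.ndarray:
        """Sorted unique labels present (background 0 included)."""
        return np.unique(self.entries[:, 3])

    @property
    def cell_labels(self) -> np.ndarray:
        labs = self.labels
        return labs[labs > 0]

    def __len__(self) -> int:
        return self.entries.shape[0]

    def relabelled(self, mapping: dict[int, int]) -> "SeedSet":
        """Seed set with labels substituted through ``mapping`` (a bijection
        on the present labels); order and coordinates unchanged."""
        out = self.entries.copy()
        out[:, 3] = [mapping[int(l)] for l in self.entries[:, 3]]
        return SeedSet(out)

    def issues(self, grid: ImageGrid, require_labels: bool = True) -> list[str]:
        """Contract violations of this seed set against ``grid``.

        Empty list iff the invariants hold: all coordinates in bounds,
        no coordinate carries two labels and, when ``require_labels``
        (the segmentation-level contract), at least one background and
        one cell seed present.  A label may repeat across entries — one
        cell seeded in several places or slices — subject to the
        conflict rule.
        """
        problems: list[str] = []
        T, H, W = grid.shape
        ent = self.entries
        for i, (t, r, c, lab) in enumerate(ent):
            if not (0 <= t < T and 0 <= r < H and 0 <= c < W):
                problems.append(
                    f"entry {i}: seed (t={t}, row={r}, col={c}, label={lab}) outside grid {grid.shape}"
                )
        coord_label: dict[tuple[int, int, int], tuple[int, int]] = {}
        for i, (t, r, c, lab) in enumerate(ent):
            key = (int(t), int(r), int(c))
            if key in coord_label and coord_label[key][1] != int(lab):
                j = coord_label[key][0]
                problems.append(
                    f"entry {i}: coordinate {key} labelled {lab} conflicts with entry {j} labelled {coord_label[key][1]}"
                )
            else:
                coord_label.setdefault(key, (i, int(lab)))
        if require_labels:
            labs = set(int(l) for l in ent[:, 3])
            if 0 not in labs:
                problems.append("no background seed (label 0) present")
            if not any(l > 0 for l in labs):
                problems.append("no cell seed (label >= 1) present")
        return problems

    def validate(self, grid: ImageGrid, require_labels: bool = True) -> None:
        problems = self.issues(grid, require_labels=require_labels)
        if problems:
            raise SeedValidationError("; ".join(problems))


@dataclass(frozen=True)
class CostModel:
    """Path-cost rule for the forest computation.

    Arc weight is the absolute intensity difference ``|I(p) - I(q)|``
    (times the temporal scale for cross-frame arcs), computed on the
    intensities after optional Gaussian pre-smoothing.  ``path_rule`` is
    ``"max"`` (cost of a path = largest arc weight on it; the canonical,
    watershed-like choice for object delineation) or ``"additive"``
    (sum of arc weights).  Seeds start with cost ``seed_handicap``.
    """

    path_rule: str = "max"
    smoothing_sigma: float = 0.0
    seed_handicap: float = 0.0

    def __post_init__(self) -> None:
        if self.path_rule not in ("max", "additive"):
            raise ValueError(f"path_rule must be 'max' or 'additive', got {self.path_rule!r}")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.seed_handicap < 0:
            raise ValueError("seed_handicap must be >= 0")


@dataclass(frozen=True)
class IFTResult:
    """Optimum-path forest over an image grid.

    All maps have the grid's (T, H, W) shape.  ``pred_map`` and
    ``root_map`` hold flat node indices (``t*H*W + r*W + c``); seeds have
    predecessor -1 and are their own roots.  ``hop_map`` is the number of
    arcs on the optimal path (part of the deterministic tie key).
    """

    label_map: np.ndarray
    cost_map: np.ndarray
    pred_map: np.ndarray
    root_map: np.ndarray
    hop_map: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_map.shape
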