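"""Synthetic TIRF spreading stacks with exact ground truth.

Each phantom cell is a growing, irregularly-bounded footprint whose area
follows a logistic law A(t) = A_max / (1 + exp(-k (t - t0))) — the
sigmoid-to-plateau shape of measured spreading curves.  Cells get
individual plateau intensities drawn from a uniform range, emulating the
cell-to-cell brightness variability that makes real TIRF segmentation
non-trivial.  Frames are background + cell plateaus, optionally Poisson
resampled (shot noise) and with additive Gaussian read noise; the ground
truth (label volume and analytic areas) is recorded pre-noise.

Not modelled: evanescent-field depth, PSF blur, photobleaching, cell
migration or collisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageGrid, SeedSet
from .quantify import AreaTable, compute_areas, logistic_area
from .segmentation import SegmentationVolume

__all__ = [
    "CellSimParams",
    "PhantomStack",
    "simulate_spreading_stack",
    "ground_truth_areas",
    "analytic_areas",
    "default_seed_annotation",
]

_MAX_HARMONIC = 5  # low-order boundary ripple only


@dataclass(frozen=True)
class CellSimParams:
    """One simulated cell.

    ``harmonic_amps``/``harmonic_phases`` define the boundary ripple
    r(theta) = r0 * (1 + sum_m amp_m cos(m theta + phase_m)) for
    m = 2..5; the base radius r0(t) is chosen so the enclosed area is
    exactly the logistic A(t) despite the ripple.
    """

    center: tuple[float, float]  # (row, col) px
    a_max_um2: float
    k_per_s: float
    t0_s: float
    intensity: float
    harmonic_amps: tuple[float, ...] = ()
    harmonic_phases: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.a_max_um2 <= 0 or self.k_per_s <= 0:
            raise ValueError("A_max and k must be positive")
        if sum(abs(a) for a in self.harmonic_amps) >= 1.0:
            raise ValueError("total boundary ripple amplitude must be < 1")
        if len(self.harmonic_amps) != len(self.harmonic_phases):
            raise ValueError("harmonic amps and phases must pair up")

    def area_um2(self, t_s) -> np.ndarray:
        """Analytic (pre-noise) area at time t."""
        return logistic_area(t_s, self.a_max_um2, self.k_per_s, self.t0_s)

    def _ripple_factor(self) -> float:
        # area of the rippled region = pi r0^2 (1 + sum a_m^2 / 2)
        return 1.0 + sum(a * a for a in self.harmonic_amps) / 2.0

    def base_radius_um(self, t_s) -> np.ndarray:
        return np.sqrt(self.area_um2(t_s) / (math.pi * self._ripple_factor()))

    def max_radius_um(self) -> float:
        """Upper bound on the boundary radius over all times and angles."""
        r0 = math.sqrt(self.a_max_um2 / (math.pi * self._ripple_factor()))
        return r0 * (1.0 + sum(abs(a) for a in self.harmonic_amps))

    def mask(self, t_s: float, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Boolean footprint on a (H, W) frame at time ``t_s``."""
        H, W = shape
        r0_px = float(self.base_radius_um(t_s)) / pixel_size_um
        if r0_px <= 0:
            return np.zeros(shape, dtype=bool)
        rmax_px = r0_px * (1.0 + sum(abs(a) for a in self.harmonic_amps)) + 1.0
        cr, cc = self.center
        r_lo = max(int(math.floor(cr - rmax_px)), 0)
        r_hi = min(int(math.ceil(cr + rmax_px)) + 1, H)
        c_lo = max(int(math.floor(cc - rmax_px)), 0)
        c_hi = min(int(math.ceil(cc + rmax_px)) + 1, W)
        out = np.zeros(shape, dtype=bool)
        if r_lo >= r_hi or c_lo >= c_hi:
            return out
        yy = np.arange(r_lo, r_hi)[:, None] - cr
        xx = np.arange(c_lo, c_hi)[None, :] - cc
        dist = np.hypot(yy, xx)
        theta = np.arctan2(yy, xx)
        radial = np.full(theta.shape, r0_px)
        for m, (amp, phase) in enumerate(zip(self.harmonic_amps, self.harmonic_phases), start=2):
            radial += r0_px * amp * np.cos(m * theta + phase)
        out[r_lo:r_hi, c_lo:c_hi] = dist <= radial
        return out


@dataclass(frozen=True)
class PhantomStack:
    """A simulated stack plus everything needed to score a segmentation."""

    grid: ImageGrid
    truth: SegmentationVolume
    cells: tuple[CellSimParams, ...]
    noise: dict
    rng_seed: int | None
    pixel_size_um: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def _auto_cells(
    n_cells: int,
    shape: tuple[int, int],
    pixel_size_um: float,
    a_max_range_um2: tuple[float, float],
    k_per_s: float,
    t0_range_s: tuple[float, float],
    intensity_range: tuple[float, float],
    irregularity: float,
    rng: np.random.Generator,
) -> list[CellSimParams]:
    """Place cells on a jittered lattice with non-overlap guaranteed."""
    H, W = shape
    r_max_px = math.sqrt(a_max_range_um2[1] / math.pi) / pixel_size_um * (1.0 + irregularity)
    margin = r_max_px + 2.0
    spacing = 2.0 * r_max_px + 6.0
    cols = max(int((W - 2 * margin) // spacing) + 1, 1)
    rows = max(int((H - 2 * margin) // spacing) + 1, 1)
    if rows * cols < n_cells:
        raise ValueError(
            f"cannot place {n_cells} non-overlapping cells of radius {r_max_px:.1f} px on {shape}"
        )
    jitter = max((spacing - 2.0 * r_max_px - 4.0) / 2.0, 0.0)
    cells = []
    positions = [(i, j) for i in range(rows) for j in range(cols)]
    idx = rng.choice(len(positions), size=n_cells, replace=False)
    for i in idx:
        gi, gj = positions[int(i)]
        cr = margin + gi * spacing + rng.uniform(-jitter, jitter)
        cc = margin + gj * spacing + rng.uniform(-jitter, jitter)
        amps_raw = rng.uniform(0.3, 1.0, _MAX_HARMONIC - 1)
        amps = tuple(amps_raw / amps_raw.sum() * irregularity) if irregularity > 0 else ()
        phases = tuple(rng.uniform(0, 2 * math.pi, len(amps)))
        cells.append(
            CellSimParams(
                center=(float(cr), float(cc)),
                a_max_um2=float(rng.uniform(*a_max_range_um2)),
                k_per_s=k_per_s,
                t0_s=float(rng.uniform(*t0_range_s)),
                intensity=float(rng.uniform(*intensity_range)),
                harmonic_amps=amps,
                harmonic_phases=phases,
            )
        )
    return cells


def simulate_spreading_stack(
    cells: list[CellSimParams] | None = None,
    n_cells: int = 5,
    n_frames: int = 60,
    frame_interval_s: float = 5.0,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.5,
    background_mean: float = 100.0,
    gaussian_sigma: float = 30.0,
    poisson: bool = True,
    intensity_range: tuple[float, float] = (300.0, 800.0),
    a_max_range_um2: tuple[float, float] = (300.0, 500.0),
    k_per_s: float = 0.015,
    t0_range_s: tuple[float, float] = (75.0, 125.0),
    irregularity: float = 0.1,
    rng_seed: int | None = None,
) -> PhantomStack:
    """Simulate a spreading time-lapse with known ground truth.

    Pass explicit ``cells`` for full control, or let ``n_cells`` be
    placed automatically on a jittered lattice with parameters drawn
    from the stated ranges.  Cells whose plateau footprints would
    overlap are rejected with an error naming the offending pair.
    Identical parameters and ``rng_seed`` give a bit-identical phantom.
    """
    rng = np.random.default_rng(rng_seed)
    H, W = shape
    if cells is None:
        cells = _auto_cells(
            n_cells, shape, pixel_size_um, a_max_range_um2, k_per_s, t0_range_s,
            intensity_range, irregularity, rng,
        )
    cells = list(cells)
    for c in cells:
        if c.intensity <= background_mean:
            raise ValueError("cell intensity must exceed the background mean")
    # pairwise disjointness at plateau size
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            d = math.hypot(
                cells[i].center[0] - cells[j].center[0],
                cells[i].center[1] - cells[j].center[1],
            )
            reach = (cells[i].max_radius_um() + cells[j].max_radius_um()) / pixel_size_um
            if d <= reach:
                raise ValueError(
                    f"cells {i + 1} and {j + 1} overlap at full spread "
                    f"(centres {d:.1f} px apart, combined reach {reach:.1f} px)"
                )

    times = np.arange(n_frames) * frame_interval_s
    clean = np.full((n_frames, H, W), float(background_mean))
    labels = np.zeros((n_frames, H, W), dtype=np.int64)
    for t_idx, t_s in enumerate(times):
        for lab, cell in enumerate(cells, start=1):
            m = cell.mask(float(t_s), shape, pixel_size_um)
            labels[t_idx][m] = lab
            clean[t_idx][m] = cell.intensity

    noisy = clean
    if poisson:
        noisy = rng.poisson(noisy).astype(np.float64)
    if gaussian_sigma > 0:
        noisy = noisy + rng.normal(0.0, gaussian_sigma, noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    spacing = (frame_interval_s, pixel_size_um, pixel_size_um)
    grid = ImageGrid(noisy, spacing=spacing)
    truth = SegmentationVolume(
        labels=labels,
        provenance={"source": "phantom", "rng_seed": rng_seed, "n_cells": len(cells)},
    )
    noise = {
        "background_mean": background_mean,
        "gaussian_sigma": gaussian_sigma,
        "poisson": poisson,
    }
    return PhantomStack(
        grid=grid, truth=truth, cells=tuple(cells), noise=noise,
        rng_seed=rng_seed, pixel_size_um=pixel_size_um,
    )


def ground_truth_areas(phantom: PhantomStack) -> AreaTable:
    """Pixel-count areas of the true label volume, on the phantom's
    calibration — the same counting the measurement path applies."""
    return compute_areas(
        phantom.truth,
        pixel_area_um2=phantom.pixel_size_um**2,
        frame_interval_s=phantom.grid.frame_interval_s,
    )


def analytic_areas(phantom: PhantomStack) -> "pandas.DataFrame":
    """Continuous logistic areas per cell and frame (no discretisation)."""
    import pandas as pd

    times = phantom.grid.times_s()
    rows = []
    for lab, cell in enumerate(phantom.cells, start=1):
        for t_idx, t_s in enumerate(times):
            rows.append((lab, t_idx, float(t_s), float(cell.area_um2(t_s))))
    return pd.DataFrame(rows, columns=["cell_label", "frame", "time_s", "area_um2"])


def default_seed_annotation(
    phantom: PhantomStack,
    per_cell_seed_count: int = 3,
    n_background: int = 10,
    background_margin_px: float = 8.0,
    rng_seed: int | None = None,
) -> SeedSet:
    """Stand-in for the user's manual seed clicks, drawn from the truth.

    For each cell, ``per_cell_seed_count`` interior points of its region
    in the first frame where it is visible; background points are
    sampled at least ``background_margin_px`` away from every cell's
    footprint at any time, in frame 0.
    """
    rng = np.random.default_rng(rng_seed)
    labels = phantom.truth.labels
    entries = []
    for lab in range(1, len(phantom.cells) + 1):
        visible = np.flatnonzero((labels == lab).any(axis=(1, 2)))
        if visible.size == 0:
            raise ValueError(f"cell {lab} never visible; cannot place its seeds")
        t = int(visible[0])
        mask = labels[t] == lab
        interior = ndimage.binary_erosion(mask)
        if not interior.any():
            interior = mask
        rr, cc = np.nonzero(interior)
        take = min(per_cell_seed_count, rr.size)
        pick = rng.choice(rr.size, size=take, replace=False)
        for i in pick:
            entries.append((t, int(rr[i]), int(cc[i]), lab))

    footprint = (labels > 0).any(axis=0)
    dist = ndimage.distance_transform_edt(~footprint)
    far = dist >= background_margin_px
    if not far.any():
        far = dist == dist.max()
    rr, cc = np.nonzero(far)
    take = min(n_background, rr.size)
    pick = rng.choice(rr.size, size=take, replace=False)
    for i in pick:
        entries.append((0, int(rr[i]), int(cc[i]), 0))
    return SeedSet.from_entries(entries)
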