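"""Contact-area quantification and the surrounding numerics.

Turns label volumes into per-cell area time-series (exportable as CSV),
aggregates cohorts of cells into spreading curves (mean area ± s.e.m.
per frame), compares groups with the pooled two-tailed Student's t-test,
and implements two small normalisations used alongside the imaging:
western-blot loading correction against an actin reference lane, and
R/R0 normalisation of paired fluorescence ratio traces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .segmentation import SegmentationVolume

__all__ = [
    "AreaTable",
    "SpreadingCurve",
    "compute_areas",
    "export_csv",
    "read_area_csv",
    "aggregate_curves",
    "pooled_ttest",
    "compare_groups",
    "normalize_blot",
    "normalize_ratio_trace",
    "fit_logistic",
    "logistic_area",
]

_AREA_COLUMNS = ["cell_label", "frame", "time_s", "area_px", "area_um2"]


@dataclass(frozen=True)
class AreaTable:
    """Per-cell, per-frame contact areas with calibration metadata.

    ``data`` columns: cell_label, frame, time_s, area_px, area_um2, one
    row per (cell_label, frame) pair — explicit zeros where a label is
    absent from a frame.  ``pixel_area_um2`` and ``frame_interval_s``
    record the calibration the areas were computed with.
    """

    data: pd.DataFrame
    pixel_area_um2: float = 1.0
    frame_interval_s: float = 5.0

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != _AREA_COLUMNS:
            raise ValueError(f"area table columns must be {_AREA_COLUMNS}, got {list(df.columns)}")
        if self.pixel_area_um2 <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be positive")
        df = df.astype(
            {"cell_label": np.int64, "frame": np.int64, "time_s": float,
             "area_px": np.int64, "area_um2": float}
        )
        df = df.sort_values(["cell_label", "frame"], kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "data", df)

    @property
    def cell_labels(self) -> np.ndarray:
        return np.unique(self.data["cell_label"].to_numpy())

    def trace(self, cell_label: int) -> pd.DataFrame:
        return self.data[self.data["cell_label"] == cell_label].reset_index(drop=True)


def compute_areas(
    seg: SegmentationVolume | np.ndarray,
    pixel_area_um2: float = 1.0,
    frame_interval_s: float = 5.0,
    include_background: bool = False,
) -> AreaTable:
    """Count each label's pixels in every frame.

    The area of cell ``l`` at frame ``t`` is the number of pixels
    labelled ``l`` there; physical area is ``area_px * pixel_area_um2``.
    Background (label 0) is excluded unless ``include_background``; a
    label missing from a frame gets an explicit zero row.  Per frame,
    background + all cell areas always sum to H*W pixels.
    """
    if pixel_area_um2 <= 0 or frame_interval_s <= 0:
        raise ValueError("calibration must be positive")
    labels = seg.labels if isinstance(seg, SegmentationVolume) else np.asarray(seg)
    if labels.ndim == 2:
        labels = labels[np.newaxis]
    T = labels.shape[0]
    labs = np.unique(labels)
    if not include_background:
        labs = labs[labs > 0]
    nmax = int(labels.max()) + 1
    rows = []
    for t in range(T):
        counts = np.bincount(labels[t].ravel(), minlength=nmax)
        for lab in labs:
            px = int(counts[lab])
            rows.append((int(lab), t, t * frame_interval_s, px, px * pixel_area_um2))
    df = pd.DataFrame(rows, columns=_AREA_COLUMNS)
    return AreaTable(df, pixel_area_um2=pixel_area_um2, frame_interval_s=frame_interval_s)


def _format_number(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def export_csv(table: AreaTable, destination) -> None:
    """Write an area table as CSV.

    Fixed dialect: header ``cell_label,frame,time_s,area_px,area_um2``,
    comma separator, '.' decimal point, UTF-8, LF line endings, rows
    sorted by (cell_label, frame).  Floats are written with the shortest
    representation that round-trips, so write -> read -> write is
    byte-identical.
    """
    buf = io.StringIO()
    buf.write(",".join(_AREA_COLUMNS) + "\n")
    for row in table.data.itertuples(index=False):
        buf.write(
            f"{row.cell_label},{row.frame},{_format_number(row.time_s)},"
            f"{row.area_px},{_format_number(row.area_um2)}\n"
        )
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_bytes(text.encode("utf-8"))


def read_area_csv(source, pixel_area_um2: float | None = None, frame_interval_s: float | None = None) -> AreaTable:
    """Read back a CSV written by :func:`export_csv`.

    Calibration is reconstructed from the data itself when not given
    (pixel area from the first nonzero row's um2/px ratio, frame
    interval from the time column)."""
    df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in _AREA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"area CSV missing columns: {missing}")
    df = df[_AREA_COLUMNS]
    if pixel_area_um2 is None:
        nz = df[df["area_px"] > 0]
        pixel_area_um2 = float(nz["area_um2"].iloc[0] / nz["area_px"].iloc[0]) if len(nz) else 1.0
    if frame_interval_s is None:
        pos = df[df["frame"] > 0]
        frame_interval_s = float(pos["time_s"].iloc[0] / pos["frame"].iloc[0]) if len(pos) else 5.0
    return AreaTable(df, pixel_area_um2=pixel_area_um2, frame_interval_s=frame_interval_s)


@dataclass(frozen=True)
class SpreadingCurve:
    """Cohort spreading kinetics: per frame, the number of contributing
    cells, mean contact area and its standard error (sample sd / sqrt n;
    NaN where n < 2, which flags an undefined s.e.m.)."""

    data: pd.DataFrame  # columns: frame, time_s, n, mean_um2, sd_um2, sem_um2
    group: str = ""
    alignment: str = "first_frame"


def aggregate_curves(
    tables: Sequence[AreaTable],
    alignment: str = "first_frame",
    offsets: Mapping[tuple[int, int], int] | None = None,
    group: str = "",
) -> SpreadingCurve:
    """Pool every cell of every table into a mean ± s.e.m. curve.

    ``alignment='first_frame'`` keeps recorded frame indices (all
    recordings start at cell landing); ``alignment='custom'`` shifts
    each cell by ``offsets[(table_index, cell_label)]`` frames.  Cells
    absent from a frame simply do not contribute there, and the per-
    frame ``n`` makes that visible.
    """
    if not tables:
        raise ValueError("no area tables given")
    interval = tables[0].frame_interval_s
    for t in tables[1:]:
        if t.frame_interval_s != interval:
            raise ValueError("all tables must share the frame interval")
    if alignment not in ("first_frame", "custom"):
        raise ValueError(f"unknown alignment {alignment!r}")
    if alignment == "custom" and offsets is None:
        raise ValueError("custom alignment requires per-cell offsets")

    pieces = []
    for i, tab in enumerate(tables):
        df = tab.data[["cell_label", "frame", "area_um2"]].copy()
        if alignment == "custom":
            df["frame"] = df.apply(
                lambda r: r["frame"] - offsets.get((i, int(r["cell_label"])), 0), axis=1
            )
        df["cell_id"] = [f"{i}:{l}" for l in df["cell_label"]]
        pieces.append(df)
    pooled = pd.concat(pieces, ignore_index=True)

    grp = pooled.groupby("frame")["area_um2"]
    out = grp.agg(n="size", mean_um2="mean", sd_um2=lambda x: x.std(ddof=1)).reset_index()
    if out.empty:
        raise ValueError("no overlapping frames across cells")
    out["sem_um2"] = out["sd_um2"] / np.sqrt(out["n"])
    out["time_s"] = out["frame"] * interval
    out = out[["frame", "time_s", "n", "mean_um2", "sd_um2", "sem_um2"]]
    return SpreadingCurve(out, group=group, alignment=alignment)


def pooled_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t with the two-tailed p.

    df = n_a + n_b - 2.  Degenerate zero-variance cases: equal means
    give (0, 1); unequal means give (±inf, 0) — a flagged-degenerate
    outcome rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return (np.inf if diff > 0 else -np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def compare_groups(
    tables_a: Sequence[AreaTable],
    tables_b: Sequence[AreaTable],
    frame: int | None = None,
    window: tuple[int, int] | None = None,
) -> tuple[float, float]:
    """Pooled two-tailed Student's t between two cohorts of cells.

    Each cell contributes its area at ``frame``, or its mean area over
    the inclusive frame ``window``.  Exactly one of the two must be
    given.
    """
    if (frame is None) == (window is None):
        raise ValueError("give exactly one of frame= or window=")

    def per_cell_values(tables: Sequence[AreaTable]) -> list[float]:
        vals = []
        for tab in tables:
            for lab in tab.cell_labels:
                tr = tab.trace(int(lab))
                if frame is not None:
                    sel = tr[tr["frame"] == frame]["area_um2"]
                else:
                    lo, hi = window
                    sel = tr[(tr["frame"] >= lo) & (tr["frame"] <= hi)]["area_um2"]
                if len(sel):
                    vals.append(float(sel.mean()))
        return vals

    return pooled_ttest(per_cell_values(tables_a), per_cell_values(tables_b))


def normalize_blot(table: pd.DataFrame) -> pd.DataFrame:
    """Loading-correct densitometric antibody signals against actin.

    The reference lane's actin is set to 1; every lane's actin is
    divided by it, and each antibody signal is divided by its lane's
    normalised actin — so unequal loading no longer inflates or deflates
    the antibody readout.  Expects columns ``lane``, ``antibody_signal``,
    ``actin_signal``, ``is_reference`` (exactly one true).  Returns the
    table with ``norm_actin`` and ``adjusted_signal`` columns added.
    """
    required = {"lane", "antibody_signal", "actin_signal", "is_reference"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"blot table missing columns: {sorted(missing)}")
    if (table["actin_signal"] <= 0).any() or (table["antibody_signal"] <= 0).any():
        raise ValueError("all blot signals must be positive")
    ref = table[table["is_reference"].astype(bool)]
    if len(ref) != 1:
        raise ValueError(f"exactly one reference lane required, got {len(ref)}")
    actin_ref = float(ref["actin_signal"].iloc[0])
    out = table.copy()
    out["norm_actin"] = out["actin_signal"] / actin_ref
    out["adjusted_signal"] = out["antibody_signal"] / out["norm_actin"]
    return out


def normalize_ratio_trace(
    numerator: Sequence[float],
    denominator: Sequence[float],
    baseline_window: int = 1,
    detrend: bool = False,
) -> np.ndarray:
    """Normalise a paired-fluorescence ratio trace to its baseline (R/R0).

    R = numerator/denominator pointwise; R0 is the mean of R over the
    first ``baseline_window`` samples, so the output's baseline mean is
    exactly 1 regardless of expression level in either channel.  With
    ``detrend``, a line fitted to the baseline window is subtracted from
    R (then renormalised) to remove a slow drift; off by default.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape or num.ndim != 1:
        raise ValueError("numerator and denominator must be 1-D traces of equal length")
    zeros = np.flatnonzero(den == 0)
    if zeros.size:
        raise ValueError(f"denominator is zero at sample index {zeros[0]}")
    if not (1 <= baseline_window <= num.size):
        raise ValueError("baseline_window must cover >= 1 sample at the trace start")
    r = num / den
    if detrend:
        idx = np.arange(baseline_window, dtype=float)
        if baseline_window >= 2:
            slope, intercept = np.polyfit(idx, r[:baseline_window], 1)
            r = r - slope * np.arange(r.size)
    r0 = r[:baseline_window].mean()
    if r0 == 0:
        raise ValueError("baseline mean ratio is zero; cannot normalise")
    return r / r0


def logistic_area(t: np.ndarray, a_max: float, k: float, t0: float) -> np.ndarray:
    """Logistic spreading law A(t) = A_max / (1 + exp(-k (t - t0)))."""
    return a_max / (1.0 + np.exp(-k * (np.asarray(t, dtype=float) - t0)))


def fit_logistic(time_s: Sequence[float], area_um2: Sequence[float]) -> dict[str, float]:
    """Least-squares fit of the logistic spreading law to a curve.

    Returns ``{'a_max': ..., 'k': ..., 't0': ...}``.  Initialised from
    the curve itself (plateau = max, midpoint = time of half-plateau).
    """
    t = np.asarray(time_s, dtype=float)
    a = np.asarray(area_um2, dtype=float)
    a_max0 = float(a.max())
    t0_0 = float(t[np.argmin(np.abs(a - a_max0 / 2))])
    span = max(float(t.max() - t.min()), 1.0)
    p0 = (a_max0, 4.0 / span, t0_0)
    popt, _ = optimize.curve_fit(logistic_area, t, a, p0=p0, maxfev=20000)
    return {"a_max": float(popt[0]), "k": float(popt[1]), "t0": float(popt[2])}
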