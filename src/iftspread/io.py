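"""File formats: multi-page TIFF stacks, seed files, provenance JSON.

Calibration (pixel size, frame interval) always comes from explicit
configuration, never from TIFF resolution tags — those are unreliable
across writers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageGrid, SeedSet

__all__ = [
    "read_stack",
    "write_stack",
    "write_label_stack",
    "read_seed_file",
    "write_seed_file",
    "write_provenance",
]

_SEED_COLUMNS = ["t", "row", "col", "label"]


def read_stack(
    path, frame_interval_s: float = 5.0, pixel_size_um: float = 1.0
) -> ImageGrid:
    """Read a single-channel multi-page TIFF as a (T, H, W) grid.

    Accepts 8/16-bit integer or 32/64-bit float pages; RGB or
    multi-channel files are rejected.  A one-page file becomes a T=1
    volume.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        if any(ax in axes for ax in ("S", "C")):
            raise ValueError(
                f"{path.name}: multi-channel/RGB TIFF (axes {series.axes!r}) is unsupported; "
                "provide a single-channel stack"
            )
        arr = series.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected 2-D pages, got array of shape {arr.shape}")
    return ImageGrid(arr, spacing=(frame_interval_s, pixel_size_um, pixel_size_um))


def write_stack(path, grid: ImageGrid | np.ndarray, dtype=np.uint16) -> None:
    """Write a (T, H, W) volume as a multi-page TIFF of ``dtype``."""
    values = grid.values if isinstance(grid, ImageGrid) else np.asarray(grid)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        values = np.clip(np.rint(values), info.min, info.max)
    tifffile.imwrite(path, values.astype(dtype), photometric="minisblack")


def write_label_stack(path, labels: np.ndarray) -> None:
    """Write a label volume as 16-bit multi-page TIFF, labels verbatim."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("labels out of uint16 range")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")


def read_seed_file(path) -> SeedSet:
    """Read seeds from CSV (header ``t,row,col,label``) or JSON (a list
    of records with those fields).  Parse errors name the offending
    line/record; the seed set is structurally validated on construction.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path.name}: JSON seed file must be a list of records")
        entries = []
        for i, rec in enumerate(records):
            try:
                entries.append([int(rec[k]) for k in _SEED_COLUMNS])
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path.name}: record {i} invalid ({exc})") from exc
        if not entries:
            raise ValueError(f"{path.name}: seed file contains no seeds")
        return SeedSet.from_entries(entries)

    df = pd.read_csv(path)
    missing = [c for c in _SEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: seed CSV missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path.name}: seed file contains no seeds")
    for col in _SEED_COLUMNS:
        bad = df[col].map(lambda v: float(v) != int(v) if np.isfinite(v) else True)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path.name}: non-integer value in column {col!r} at line {line}")
    return SeedSet(df[_SEED_COLUMNS].to_numpy(dtype=np.int64))


def write_seed_file(path, seeds: SeedSet) -> None:
    """Write seeds as CSV or JSON (by file extension), round-trippable
    through :func:`read_seed_file`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {k: int(v) for k, v in zip(_SEED_COLUMNS, row)} for row in seeds.entries
        ]
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        df = pd.DataFrame(seeds.entries, columns=_SEED_COLUMNS)
        df.to_csv(path, index=False, lineterminator="\n")


def write_provenance(path, provenance: dict) -> None:
    """Serialise a provenance record as stable, human-readable JSON."""
    Path(path).write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
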