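"""File I/O for centerline time series.

Two dialects are supported:

* **Per-cell TSV** (tab-separated, header row) with columns
  ``frame, time_s, point_index, s_um, x_um, y_um`` — one file per cell.
  Files whose frames carry unequal point counts, or whose arc coordinate is
  not a shared uniform grid, are treated as raw polylines and spline-resampled
  onto a uniform grid at read time.
* **HDF5 bundle** — one file per experiment holding many cells under
  ``/cells/<cell_id>`` with datasets ``times``, ``arc_grid``, ``x``, ``y``
  and attributes ``fps``, ``body_length``, ``group``, ``mouse_id``.

A ``z_um`` column is rejected outright: the pipeline is strictly planar and
silently dropping a third coordinate would hide a modelling error.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .centerline import CenterlineSeries, resample_series
from .errors import DataError, FormatError, InsufficientDataError

__all__ = ["read_centerlines", "write_centerlines", "save_bundle", "load_bundle"]

_REQUIRED_COLUMNS = ["frame", "time_s", "point_index", "s_um", "x_um", "y_um"]


def read_centerlines(
    path: str | os.PathLike,
    format: str = "tsv",
    *,
    n_points: int = 100,
    smoothing: float = 0.0,
    fps: float | None = None,
    body_length: float | None = None,
    validate: bool = True,
) -> CenterlineSeries:
    """Read a per-cell centerline file.

    Parameters
    ----------
    path : path to the file.
    format : dialect tag, ``"tsv"`` (the only flat-file dialect).
    n_points : arc-grid size used when resampling raw polylines.
    smoothing : spline smoothing factor for resampling (0 = interpolate).
    fps : override the frame rate inferred from the time stamps.
    body_length : override the flagellum length (μm).
    validate : run the structural invariant checks after reading.
    """
    if format != "tsv":
        raise FormatError(f"unknown centerline format {format!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    if "z_um" in df.columns:
        raise FormatError("3D centerlines (z_um column) are not supported")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")

    if df.duplicated(subset=["frame", "point_index"]).any():
        raise DataError("duplicated (frame, point_index) rows")
    frames = df["frame"].to_numpy()
    frame_ids = pd.unique(frames)
    n_frames = len(frame_ids)
    if n_frames < 3:
        raise InsufficientDataError(f"only {n_frames} frames in {path}")

    grouped = df.groupby("frame", sort=True)
    times = grouped["time_s"].first().to_numpy(dtype=float)
    if grouped["time_s"].nunique().max() > 1:
        raise DataError("inconsistent time stamps within a frame")
    if len(times) != n_frames or not np.all(np.diff(times) > 0):
        raise DataError("frame times must be strictly increasing (duplicated or shuffled frames?)")

    counts = grouped.size().to_numpy()
    if counts.min() < 5:
        raise InsufficientDataError("fewer than 5 points in at least one frame")

    inferred_fps = fps if fps is not None else 1.0 / float(np.median(np.diff(times)))

    uniform = counts.min() == counts.max()
    if uniform:
        m = int(counts[0])
        sort_df = df.sort_values(["frame", "point_index"])
        s = sort_df["s_um"].to_numpy(dtype=float).reshape(n_frames, m)
        # shared uniform grid?
        ds = np.diff(s[0])
        shared = np.allclose(s, s[0], atol=1e-6) and np.allclose(ds, ds[0], rtol=0.02)
        if shared:
            x = sort_df["x_um"].to_numpy(dtype=float).reshape(n_frames, m)
            y = sort_df["y_um"].to_numpy(dtype=float).reshape(n_frames, m)
            series = CenterlineSeries(
                times=times,
                arc_grid=s[0],
                x=x,
                y=y,
                fps=inferred_fps,
                body_length=body_length if body_length is not None else float(s[0][-1]),
            )
            return series.validate() if validate else series
        uniform = False

    # raw polylines of unequal length or non-shared arc grids: resample
    frames_xy = [
        g[["x_um", "y_um"]].to_numpy(dtype=float)
        for _, g in df.sort_values(["frame", "point_index"]).groupby("frame", sort=True)
    ]
    series = resample_series(
        frames_xy,
        times,
        n_points=n_points,
        body_length=body_length,
        fps=inferred_fps,
        smoothing=smoothing,
    )
    return series.validate() if validate else series


def write_centerlines(c: CenterlineSeries, path: str | os.PathLike) -> None:
    """Write a centerline series in the per-cell TSV dialect."""
    n, m = c.n_frames, c.n_points
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n), m),
            "time_s": np.repeat(c.times, m),
            "point_index": np.tile(np.arange(m), n),
            "s_um": np.tile(c.arc_grid, n),
            "x_um": c.x.ravel(),
            "y_um": c.y.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def save_bundle(
    path: str | os.PathLike,
    cells: dict[str, CenterlineSeries],
    metadata: dict[str, dict] | None = None,
) -> None:
    """Save several cells into one HDF5 experiment bundle.

    ``metadata`` maps cell id to a flat dict of scalar attributes
    (e.g. ``{"group": "wt", "mouse_id": "m1"}``).
    """
    metadata = metadata or {}
    with h5py.File(path, "w") as f:
        root = f.create_group("cells")
        for cell_id, c in cells.items():
            g = root.create_group(str(cell_id))
            g.create_dataset("times", data=c.times)
            g.create_dataset("arc_grid", data=c.arc_grid)
            g.create_dataset("x", data=c.x)
            g.create_dataset("y", data=c.y)
            g.attrs["fps"] = c.fps
            g.attrs["body_length"] = c.body_length
            for k, v in metadata.get(cell_id, {}).items():
                g.attrs[k] = v


def load_bundle(
    path: str | os.PathLike,
) -> tuple[dict[str, CenterlineSeries], dict[str, dict]]:
    """Load an HDF5 experiment bundle; returns (cells, metadata)."""
    cells: dict[str, CenterlineSeries] = {}
    metadata: dict[str, dict] = {}
    with h5py.File(path, "r") as f:
        for cell_id, g in f["cells"].items():
            cells[cell_id] = CenterlineSeries(
                times=g["times"][:],
                arc_grid=g["arc_grid"][:],
                x=g["x"][:],
                y=g["y"][:],
                fps=float(g.attrs["fps"]),
                body_length=float(g.attrs["body_length"]),
            )
            metadata[cell_id] = {
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in g.attrs.items()
                if k not in ("fps", "body_length")
            }
    return cells, metadata
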