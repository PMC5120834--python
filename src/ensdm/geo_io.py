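"""Raster and tabular I/O plus grid co-registration.

Two raster dialects are supported:

* **ESRI ASCII grid** (``.asc``) — the canonical, human-diffable text
  format used for fixtures.  Because the package's y axis increases
  downward from a top-left origin, ``yllcorner`` stores the bottom edge
  ``origin_y + nrows * cellsize``; round-trips are exact.
* **TIFF** (``.tif``/``.tiff``) — written with `tifffile`, with the grid
  geometry (cell size, origin, nodata, crs label) embedded as JSON in the
  ImageDescription tag.  Lossless within this package; not a full
  GDAL-style GeoTIFF.

Occurrence records travel as CSV with columns species,x,y and optional
label,source.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid
from .occurrences import COLUMNS, OccurrenceSet

__all__ = [
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "align_to_analysis_grid",
]

logger = logging.getLogger(__name__)

_ASC_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


# ----------------------------------------------------------------------
# ESRI ASCII grid
def _write_asc(grid: Grid, path: Path) -> None:
    vals = np.where(grid.mask, grid.values, grid.nodata)
    x0, y0 = grid.origin
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {y0 + grid.nrows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_asc(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in _ASC_KEYS or key == "nodata_value":
                if len(parts) != 2:
                    raise ValueError(f"{path}: malformed header line {line.strip()!r}")
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(v) for v in parts])
                except ValueError as exc:
                    raise ValueError(f"{path}: unparseable data line {line.strip()!r}") from exc
    missing = [k for k in _ASC_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: ASCII grid header missing keys {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise ValueError(
            f"{path}: data block is {len(rows)} rows x "
            f"{set(len(r) for r in rows) or {0}} cols, header says {nrows} x {ncols}"
        )
    nodata = header.get("nodata_value", -9999.0)
    values = np.asarray(rows, dtype=float)
    values[values == nodata] = np.nan
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] - nrows * cell)
    return Grid(values, cell_size=cell, origin=origin, nodata=nodata)


# ----------------------------------------------------------------------
# TIFF
def _write_tif(grid: Grid, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "nodata": grid.nodata,
        "crs_label": grid.crs_label,
    }
    vals = np.where(grid.mask, grid.values, grid.nodata).astype(np.float64)
    tifffile.imwrite(path, vals, description=json.dumps(meta))


def _read_tif(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    nodata = float(meta.get("nodata", -9999.0))
    values[values == nodata] = np.nan
    return Grid(
        values,
        cell_size=float(meta.get("cell_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=nodata,
        crs_label=meta.get("crs_label", "local-planar"),
    )


def write_raster(grid: Grid, path) -> Path:
    """Write a grid to ``.asc`` (text) or ``.tif``, chosen by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_asc(grid, path)
    elif suffix in (".tif", ".tiff"):
        _write_tif(grid, path)
    else:
        raise ValueError(f"unsupported raster extension {suffix!r} (use .asc or .tif)")
    return path


def read_raster(path) -> Grid:
    """Read a grid written by :func:`write_raster`; nodata maps to NaN."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return _read_asc(path)
    if suffix in (".tif", ".tiff"):
        return _read_tif(path)
    raise ValueError(f"unsupported raster extension {suffix!r} (use .asc or .tif)")


# ----------------------------------------------------------------------
# occurrences
def write_occurrences(occ: OccurrenceSet, path) -> Path:
    path = Path(path)
    occ.records.to_csv(path, index=False)
    return path


def read_occurrences(path) -> OccurrenceSet:
    """Read an occurrence CSV; rows with non-finite coordinates are dropped.

    Requires columns species,x,y; label defaults to presence and source
    to the file name.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("species", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: occurrence CSV missing required columns {missing}")
    coords = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(coords.to_numpy()).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("%s: dropped %d rows with non-finite coordinates", path, n_dropped)
    df = df.loc[ok].copy()
    df[["x", "y"]] = coords.loc[ok]
    if "label" not in df.columns:
        df["label"] = "presence"
    if "source" not in df.columns:
        df["source"] = path.name
    df["source"] = df["source"].fillna("")
    return OccurrenceSet(df[[c for c in COLUMNS if c in df.columns]])


# ----------------------------------------------------------------------
# resampling
def align_to_analysis_grid(coarse: Grid, fine_template: Grid) -> Grid:
    """Nearest-neighbour resample a coarse grid onto a fine template.

    Each fine cell takes the value of the coarse cell containing its
    centre, so no interpolated values are invented and nodata propagates.
    Fine cells whose centres fall outside the coarse extent become nodata.
    """
    if coarse.cell_size < fine_template.cell_size - 1e-12:
        raise ValueError(
            f"coarse cell_size ({coarse.cell_size}) must be >= fine "
            f"cell_size ({fine_template.cell_size})"
        )
    cx0, cy0, cx1, cy1 = coarse.bounds
    fx0, fy0, fx1, fy1 = fine_template.bounds
    if fx1 <= cx0 or fx0 >= cx1 or fy1 <= cy0 or fy0 >= cy1:
        raise ValueError("coarse grid and fine template extents are disjoint")
    rows = np.arange(fine_template.nrows)
    cols = np.arange(fine_template.ncols)
    xc, _ = fine_template.cell_center(np.zeros_like(cols), cols)
    _, yc = fine_template.cell_center(rows, np.zeros_like(rows))
    crow, _ = coarse.cell_index(np.full_like(yc, coarse.origin[0]), yc)
    _, ccol = coarse.cell_index(xc, np.full_like(xc, coarse.origin[1]))
    out = np.full(fine_template.shape, np.nan)
    rin = (crow >= 0) & (crow < coarse.nrows)
    cin = (ccol >= 0) & (ccol < coarse.ncols)
    rr, cc = np.meshgrid(crow[rin], ccol[cin], indexing="ij")
    block = coarse.values[rr, cc]
    out[np.ix_(rin, cin)] = block
    return Grid(
        out,
        cell_size=fine_template.cell_size,
        origin=fine_template.origin,
        nodata=fine_template.nodata,
        crs_label=fine_template.crs_label,
    )
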