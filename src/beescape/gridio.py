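"""Raster and table I/O.

Grids travel as plain 2-D numpy arrays inside the package. On disk two formats
are supported: ESRI ASCII grid (``.asc``, human-readable, the format used for
all shipped fixtures) and TIFF (``.tif``, one band per array, via tifffile).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["read_ascii_grid", "write_ascii_grid", "read_tiff", "write_tiff"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    cell_size: float = 25.0,
    xll: float = 0.0,
    yll: float = 0.0,
    nodata: float = -9999,
    fmt: str = "%.10g",
) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost row)."""
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("ASCII grid requires a 2-D array")
    header = (
        f"ncols {grid.shape[1]}\n"
        f"nrows {grid.shape[0]}\n"
        f"xllcorner {xll:.10g}\n"
        f"yllcorner {yll:.10g}\n"
        f"cellsize {cell_size:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns ``(grid, cell_size)``."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (*_HEADER_KEYS, "nodata_value"):
                meta[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        grid = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in meta:
            raise ValueError(f"missing ASCII grid header field {key!r} in {path}")
    if grid.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(
            f"grid shape {grid.shape} does not match header "
            f"({int(meta['nrows'])}, {int(meta['ncols'])}) in {path}"
        )
    if "nodata_value" in meta:
        grid[grid == meta["nodata_value"]] = np.nan
    return grid, meta["cellsize"]


def write_tiff(path: str | Path, *bands: np.ndarray) -> None:
    """Write one or more congruent 2-D arrays as a multi-band float32 TIFF."""
    stack = np.stack([np.asarray(b, dtype=np.float32) for b in bands])
    tifffile.imwrite(path, stack)


def read_tiff(path: str | Path) -> np.ndarray:
    """Read a TIFF written by :func:`write_tiff`; returns ``(bands, r, c)``."""
    arr = tifffile.imread(path)
    return arr if arr.ndim == 3 else arr[None, ...]
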