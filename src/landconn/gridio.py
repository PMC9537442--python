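"""Plain-text raster and table I/O.

Rasters use the ESRI ASCII grid format (.asc): a six-line header (ncols,
nrows, xllcorner, yllcorner, cellsize, NODATA_value) followed by rows of
whitespace-separated values, row 0 at the top. Source sets are two-column CSV
(row,col) with a header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_ascii_grid(
    path: str | Path,
    grid: np.ndarray,
    cellsize: float = 1.0,
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
    nodata: float = -9999.0,
) -> None:
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    nrows, ncols = grid.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, grid, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> np.ndarray:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        grid = np.loadtxt(fh, ndmin=2)
    nrows = int(header.get("nrows", grid.shape[0]))
    ncols = int(header.get("ncols", grid.shape[1]))
    if grid.shape != (nrows, ncols):
        raise ValueError(
            f"grid shape {grid.shape} does not match header ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        grid[grid == nodata] = np.nan
    return grid


def write_sources(path: str | Path, sources: np.ndarray) -> None:
    pd.DataFrame(np.asarray(sources), columns=["row", "col"]).to_csv(path, index=False)


def read_sources(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["row", "col"]].to_numpy(dtype=np.int64)


def write_paths(path: str | Path, paths) -> None:
    """Write simulated walks as long-format CSV.

    Columns: path_id, step, row, col, termination_reason (the reason is
    repeated on every row of its path).
    """
    rows = []
    for pid, p in enumerate(paths):
        for step, (r, c) in enumerate(p.coords):
            rows.append((pid, step, r, c, p.termination_reason))
    pd.DataFrame(
        rows, columns=["path_id", "step", "row", "col", "termination_reason"]
    ).to_csv(path, index=False)
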