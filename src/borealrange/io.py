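"""Plain-text I/O: delimited tables and matrix rasters with JSON sidecars.

Rasters are written as tab-delimited row-major matrices (origin at the
northwest corner, 0-based indices) with a ``.json`` sidecar recording rows,
columns, cell area and value name — a portable, bit-stable dialect that
needs no geospatial stack.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .landscape import GridSpec, LanduseEvents

__all__ = [
    "write_raster",
    "read_raster",
    "write_climate_table",
    "read_climate_table",
    "write_events",
    "read_events",
]


def write_raster(path, values, grid: GridSpec, name: str = "value") -> None:
    """Write per-cell values as a matrix raster plus JSON sidecar."""
    path = Path(path)
    vals = pd.Series(values).reindex(grid.cell_ids)
    if vals.isna().any():
        raise ValueError("raster values missing for some grid cells")
    mat = vals.to_numpy(dtype=float).reshape(grid.rows, grid.cols)
    np.savetxt(path, mat, fmt="%.10g", delimiter="\t")
    sidecar = {
        "rows": grid.rows,
        "cols": grid.cols,
        "cell_area_km2": grid.cell_area_km2,
        "origin": "northwest",
        "order": "row-major",
        "name": name,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )


def read_raster(path) -> tuple[pd.Series, GridSpec]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = GridSpec(meta["rows"], meta["cols"], meta["cell_area_km2"])
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    if mat.shape != (grid.rows, grid.cols):
        raise ValueError(f"raster {path} shape {mat.shape} does not match sidecar")
    return pd.Series(mat.ravel(), index=pd.Index(grid.cell_ids, name="cell_id")), grid


def write_climate_table(path, grid: ClimateGrid) -> None:
    """Long-format daily climate (cell_id, date, tmin, tmean, snow_cm)."""
    frame = grid.to_frame()
    frame["date"] = pd.DatetimeIndex(frame["date"]).strftime("%Y-%m-%d")
    frame.to_csv(path, index=False, float_format="%.2f")


def read_climate_table(path) -> ClimateGrid:
    """Read and validate a long-format climate table, naming offending rows."""
    frame = pd.read_csv(path, parse_dates=["date"])
    required = {"cell_id", "date", "tmin", "tmean", "snow_cm"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    numeric = frame[["tmin", "tmean", "snow_cm"]]
    bad = frame.index[numeric.isna().any(axis=1) | ~np.isfinite(numeric).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric climate values at rows {bad[:10].tolist()}")
    bad = frame.index[frame["tmin"] > frame["tmean"] + 1e-9]
    if len(bad):
        raise ValueError(f"{path}: tmin exceeds tmean at rows {bad[:10].tolist()}")
    bad = frame.index[frame["snow_cm"] < 0]
    if len(bad):
        raise ValueError(f"{path}: negative snow depth at rows {bad[:10].tolist()}")
    return ClimateGrid.from_frame(frame)


def write_events(outdir, events: LanduseEvents) -> list[str]:
    outdir = Path(outdir)
    names = []
    for name, frame in (
        ("wells", events.wells),
        ("cutblocks", events.cutblocks),
        ("agriculture", events.agriculture),
    ):
        fname = f"{name}.csv"
        frame.to_csv(outdir / fname, index=False)
        names.append(fname)
    return names


def read_events(outdir) -> LanduseEvents:
    outdir = Path(outdir)

    def load(name):
        path = outdir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing land-use table {path}; run the simulate stage first")
        return pd.read_csv(path)

    return LanduseEvents(
        wells=load("wells"), cutblocks=load("cutblocks"), agriculture=load("agriculture")
    )
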