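"""Decadal covariate landscapes: land-use footprint, land cover and climate.

A decade labelled ``d`` covers calendar years [d, d+9].  The land-use
snapshot is taken at the decade end: well pads accumulate indefinitely (no
reclamation), cut blocks contribute only while younger than ~30 years
(browse grows out of reach afterwards, anchored at the decade start, so the
2000s exclude pre-1970 cuts), and agricultural epochs persist once
developed.  Where layered proportions exceed one, land cover (deciduous,
wetland) is reduced proportionally to its coverage so that development
functionally erases cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateCoverageError

__all__ = [
    "GridSpec",
    "LanduseEvents",
    "DecadalLandscape",
    "footprint_for_decade",
    "reconcile_landcover",
    "assemble_landscape",
    "LANDSCAPE_COLUMNS",
]

LANDSCAPE_COLUMNS = ["prop_deciduous", "prop_wetland", "prop_footprint", "wsi_mean", "gs_mean"]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular analysis grid; row-major, origin at the northwest corner.

    Cells are identified by 0-based row-major index; the reference layout is
    10 km × 1 km east–west rectangles, but any rectangle is allowed as long
    as the per-cell area is carried explicitly.
    """

    rows: int
    cols: int
    cell_area_km2: float = 10.0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_area_km2 <= 0:
            raise ValueError("cell area must be positive")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def rowcol(self, cell_id: np.ndarray):
        cid = np.asarray(cell_id)
        return cid // self.cols, cid % self.cols


def _events_frame(df, columns, allow_missing_year=False) -> pd.DataFrame:
    if df is None or len(df) == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in columns})
    f = pd.DataFrame(df).copy()
    missing = set(columns) - set(f.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    if (f["area_km2"] < 0).any():
        raise ValueError("event areas must be non-negative")
    if not allow_missing_year and f["year"].isna().any():
        raise ValueError("events must carry a year")
    return f[columns]


@dataclass
class LanduseEvents:
    """Dated land-use development events.

    ``wells`` and ``agriculture``: (cell_id, year, area_km2) with a year on
    every record; agriculture rows are epoch polygons that persist once
    developed.  ``cutblocks``: (cell_id, year, area_km2) where ``year`` may
    be NaN — a substantial fraction of real cut-block inventories lack the
    year of harvest, and undated blocks are included only on request.
    """

    wells: pd.DataFrame = None
    cutblocks: pd.DataFrame = None
    agriculture: pd.DataFrame = None

    def __post_init__(self) -> None:
        cols = ["cell_id", "year", "area_km2"]
        self.wells = _events_frame(self.wells, cols)
        self.cutblocks = _events_frame(self.cutblocks, cols, allow_missing_year=True)
        self.agriculture = _events_frame(self.agriculture, cols)


def footprint_for_decade(
    events: LanduseEvents,
    grid: GridSpec,
    decade: int,
    *,
    include_undated_cuts: bool = True,
    cutblock_age_limit: int = 30,
) -> pd.Series:
    """Per-cell total land-use footprint proportion at the end of a decade.

    Wells and agriculture are cumulative through the decade end (d+9); cut
    blocks contribute if cut in [decade − age_limit, decade end].  Layer
    areas are capped at the cell area before and after summation, which
    stands in for the union of possibly overlapping polygons.
    """
    if decade % 10 != 0:
        raise ValueError(f"unknown decade label {decade!r}: use e.g. 1970, 1980")
    end = decade + 9
    cap = grid.cell_area_km2

    def layer(df: pd.DataFrame, mask) -> pd.Series:
        sel = df.loc[mask] if len(df) else df
        area = sel.groupby("cell_id")["area_km2"].sum() if len(sel) else pd.Series(dtype=float)
        return area.clip(upper=cap)

    wells = layer(events.wells, events.wells["year"] <= end if len(events.wells) else None)
    ag = layer(
        events.agriculture,
        events.agriculture["year"] <= end if len(events.agriculture) else None,
    )
    cb = events.cutblocks
    if len(cb):
        dated = cb["year"].notna() & (cb["year"] >= decade - cutblock_age_limit) & (cb["year"] <= end)
        mask = dated | (cb["year"].isna() if include_undated_cuts else False)
    else:
        mask = None
    cuts = layer(cb, mask)

    total = (
        wells.reindex(grid.cell_ids, fill_value=0.0)
        + cuts.reindex(grid.cell_ids, fill_value=0.0)
        + ag.reindex(grid.cell_ids, fill_value=0.0)
    ).clip(upper=cap)
    prop = total / cap
    prop.index.name = "cell_id"
    prop.name = "prop_footprint"
    return prop


def reconcile_landcover(prop_footprint, prop_deciduous, prop_wetland):
    """Reduce land cover so footprint + cover does not exceed one.

    Where the summed proportion exceeds one, the excess is subtracted from
    deciduous and wetland cover in proportion to their coverage; outputs are
    floored at zero.  Conserves: footprint + adjusted cover =
    min(1, original sum).
    """
    fp = np.asarray(prop_footprint, dtype=float)
    dec = np.asarray(prop_deciduous, dtype=float)
    wet = np.asarray(prop_wetland, dtype=float)
    for name, arr in (("footprint", fp), ("deciduous", dec), ("wetland", wet)):
        if ((arr < -1e-12) | (arr > 1 + 1e-12)).any() and name != "footprint":
            raise ValueError(f"{name} proportion outside [0, 1]")
    if (fp > 1 + 1e-9).any():
        raise ValueError("footprint proportion exceeds one")
    excess = np.maximum(0.0, fp + dec + wet - 1.0)
    denom = dec + wet
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(denom > 0, dec / np.where(denom > 0, denom, 1.0), 0.0)
    dec_adj = np.maximum(0.0, dec - excess * share)
    wet_adj = np.maximum(0.0, wet - excess * (1.0 - share))
    return dec_adj, wet_adj


@dataclass
class DecadalLandscape:
    """Per-cell covariate vector for one decade.

    ``frame`` is indexed by cell_id with columns prop_deciduous,
    prop_wetland, prop_footprint (proportions in [0, 1]), wsi_mean (index
    points) and gs_mean (days).
    """

    decade: int
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = pd.DataFrame(self.frame)
        missing = set(LANDSCAPE_COLUMNS) - set(f.columns)
        if missing:
            raise ValueError(f"landscape missing columns: {sorted(missing)}")
        f = f[LANDSCAPE_COLUMNS].astype(float)
        props = f[["prop_deciduous", "prop_wetland", "prop_footprint"]]
        if ((props < -1e-9) | (props > 1 + 1e-9)).any().any():
            raise ValueError("landscape proportions outside [0, 1]")
        if (props.sum(axis=1) > 1 + 1e-9).any():
            raise ValueError("footprint + cover exceeds one after reconciliation")
        if not np.isfinite(f.to_numpy()).all():
            raise ValueError("non-finite covariate in landscape")
        self.frame = f

    @property
    def cell_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def replace(self, **columns) -> "DecadalLandscape":
        f = self.frame.copy()
        for name, values in columns.items():
            f[name] = values
        return DecadalLandscape(self.decade, f)


def _climate_means(
    table: pd.DataFrame, column: str, base_year: int, end_year: int, cells: np.ndarray
) -> pd.Series:
    """Per-cell cumulative mean of an annual index over [base, end] inclusive."""
    wide = table.pivot_table(index="cell_id", columns="year", values=column)
    wanted = np.arange(base_year, end_year + 1)
    missing_years = np.setdiff1d(wanted, wide.columns.to_numpy())
    if len(missing_years):
        raise ClimateCoverageError(
            f"{column}: missing years {missing_years[:5].tolist()} in "
            f"[{base_year}, {end_year}]"
        )
    sub = wide.reindex(cells)[wanted]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)][:5].tolist()
        raise ClimateCoverageError(f"{column}: missing annual values for cells {bad}")
    return sub.mean(axis=1)


def assemble_landscape(
    grid: GridSpec,
    events: LanduseEvents,
    landcover: pd.DataFrame,
    indices: pd.DataFrame,
    decade: int,
    *,
    wsi_base_year: int = 1961,
    gs_base_year: int = 1950,
    include_undated_cuts: bool = True,
    cutblock_age_limit: int = 30,
) -> DecadalLandscape:
    """Compose the five-covariate landscape for one decade.

    ``landcover`` carries raw per-cell prop_deciduous / prop_wetland;
    ``indices`` is the long annual table (cell_id, year, wsi, gs).  Climate
    covariates are cumulative means from the base years through the decade
    start (the "beginning of the decade of interest"); cover is reconciled
    against the footprint.
    """
    fp = footprint_for_decade(
        events,
        grid,
        decade,
        include_undated_cuts=include_undated_cuts,
        cutblock_age_limit=cutblock_age_limit,
    )
    lc = pd.DataFrame(landcover).set_index("cell_id").reindex(grid.cell_ids)
    if lc[["prop_deciduous", "prop_wetland"]].isna().any().any():
        raise ValueError("land cover missing for some grid cells")
    dec_adj, wet_adj = reconcile_landcover(
        fp.to_numpy(), lc["prop_deciduous"].to_numpy(), lc["prop_wetland"].to_numpy()
    )
    wsi = _climate_means(indices, "wsi", wsi_base_year, decade, grid.cell_ids)
    gs = _climate_means(indices, "gs", gs_base_year, decade, grid.cell_ids)
    frame = pd.DataFrame(
        {
            "prop_deciduous": dec_adj,
            "prop_wetland": wet_adj,
            "prop_footprint": fp.to_numpy(),
            "wsi_mean": wsi.to_numpy(),
            "gs_mean": gs.to_numpy(),
        },
        index=pd.Index(grid.cell_ids, name="cell_id"),
    )
    return DecadalLandscape(decade, frame)
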