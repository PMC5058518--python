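"""Winter severity and growing-season indices from daily climate series.

The winter severity index (WSI) counts days in a November–April window whose
minimum temperature falls below −17.7 °C and/or whose snow depth exceeds
38 cm; a day meeting both criteria counts once.  Growing-season length runs
from the first 5-day run of mean daily temperature ≥ 5 °C (searched from
March 1) to the first day after August 1 on which the minimum temperature
reaches −2 °C.  Decadal model covariates are cumulative means of these annual
indices from a fixed base year, and forecasts rest on per-cell ordinary
least-squares trends of the annual values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClimateCoverageError",
    "WinterSpec",
    "ClimateSeries",
    "ClimateGrid",
    "AnnualIndexSeries",
    "TrendModel",
    "compute_wsi",
    "compute_growing_season",
    "cumulative_mean",
    "fit_trend",
    "extrapolate",
    "annual_index_table",
]


class ClimateCoverageError(ValueError):
    """A required daily window has missing days (no silent imputation)."""


@dataclass(frozen=True)
class WinterSpec:
    """Thresholds and window defining the winter severity index.

    The window runs from ``start_month/start_day`` of the winter year through
    ``end_month/end_day`` of the following calendar year.  A winter is
    labelled by the year of its November.
    """

    temp_threshold_c: float = -17.7
    snow_threshold_cm: float = 38.0
    start_month: int = 11
    start_day: int = 1
    end_month: int = 4
    end_day: int = 30

    def window(self, winter_year: int) -> pd.DatetimeIndex:
        start = pd.Timestamp(winter_year, self.start_month, self.start_day)
        end = pd.Timestamp(winter_year + 1, self.end_month, self.end_day)
        if end <= start:
            raise ValueError("winter window must span the year boundary")
        return pd.date_range(start, end, freq="D")

    def qualifies(self, tmin, snow_cm):
        """Boolean day-qualification rule: cold and/or deep snow (strict)."""
        return (np.asarray(tmin) < self.temp_threshold_c) | (
            np.asarray(snow_cm) > self.snow_threshold_cm
        )


@dataclass
class ClimateSeries:
    """Daily weather record for one grid cell.

    ``frame`` is indexed by date (daily resolution, strictly increasing) with
    columns ``tmin``, ``tmean`` (°C) and ``snow_cm`` (≥ 0).
    """

    cell_id: int
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if "date" in f.columns:
            f = f.set_index("date")
        f = f.copy()
        f.index = pd.DatetimeIndex(f.index)
        missing = {"tmin", "tmean", "snow_cm"} - set(f.columns)
        if missing:
            raise ValueError(f"climate series missing columns: {sorted(missing)}")
        if not f.index.is_monotonic_increasing or f.index.has_duplicates:
            raise ValueError("dates must be strictly increasing")
        bad = f.index[f["tmin"] > f["tmean"] + 1e-9]
        if len(bad):
            raise ValueError(f"tmin > tmean on {bad[0].date()} (cell {self.cell_id})")
        if (f["snow_cm"] < 0).any():
            raise ValueError(f"negative snow depth in cell {self.cell_id}")
        self.frame = f

    def _window(self, dates: pd.DatetimeIndex, what: str) -> pd.DataFrame:
        gaps = dates.difference(self.frame.index)
        if len(gaps):
            shown = ", ".join(str(d.date()) for d in gaps[:5])
            more = "" if len(gaps) <= 5 else f" (+{len(gaps) - 5} more)"
            raise ClimateCoverageError(
                f"cell {self.cell_id}: {len(gaps)} missing days in {what} "
                f"window: {shown}{more}"
            )
        return self.frame.loc[dates]


def compute_wsi(series: ClimateSeries, winter_year: int, spec: WinterSpec | None = None) -> int:
    """Winter severity index for the winter starting in ``winter_year``.

    Counts the days in the Nov 1 – Apr 30 window with minimum temperature
    below the cold threshold and/or snow depth above the snow threshold.
    Raises :class:`ClimateCoverageError` if any day of the window is absent.
    """
    spec = spec or WinterSpec()
    sub = series._window(spec.window(winter_year), f"winter {winter_year}")
    return int(spec.qualifies(sub["tmin"], sub["snow_cm"]).sum())


def compute_growing_season(
    series: ClimateSeries,
    year: int,
    *,
    t_start_c: float = 5.0,
    run_days: int = 5,
    t_end_c: float = -2.0,
) -> int:
    """Growing-season length (days) for ``year``.

    Season starts on the first day of the first ``run_days``-day run with
    mean temperature ≥ ``t_start_c``, searched from March 1; it ends on the
    first day strictly after August 1 with minimum temperature ≤ ``t_end_c``
    (December 31 if none).  Length is end − start in whole days, end
    exclusive; 0 when no qualifying run starts, or when the end precedes the
    start.
    """
    window = pd.date_range(
        pd.Timestamp(year, 3, 1), pd.Timestamp(year, 12, 31), freq="D"
    )
    sub = series._window(window, f"growing season {year}")
    ok = (sub["tmean"].to_numpy() >= t_start_c).astype(int)
    runsum = np.convolve(ok, np.ones(run_days, dtype=int), mode="valid")
    starts = np.nonzero(runsum == run_days)[0]
    if len(starts) == 0:
        return 0
    start = window[starts[0]]
    after = (window > pd.Timestamp(year, 8, 1)) & (sub["tmin"].to_numpy() <= t_end_c)
    hits = np.nonzero(after)[0]
    end = window[hits[0]] if len(hits) else window[-1]
    return max(0, (end - start).days)


@dataclass
class AnnualIndexSeries:
    """Annual index values (WSI or growing season) for one cell."""

    cell_id: int
    values: pd.Series  # index: year (int) -> value

    def __post_init__(self) -> None:
        v = pd.Series(self.values).sort_index()
        v.index = v.index.astype(int)
        self.values = v.astype(float)

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()


def cumulative_mean(annual: AnnualIndexSeries, base_year: int, end_year: int) -> float:
    """Arithmetic mean of annual values from base_year to end_year inclusive.

    Every year in the range must be present; gaps raise an error rather than
    being imputed.
    """
    if end_year < base_year:
        raise ValueError("end_year precedes base_year")
    wanted = np.arange(base_year, end_year + 1)
    missing = np.setdiff1d(wanted, annual.values.index.to_numpy())
    if len(missing):
        raise ClimateCoverageError(
            f"cell {annual.cell_id}: missing years {missing[:5].tolist()} "
            f"in [{base_year}, {end_year}]"
        )
    return float(annual.values.loc[wanted].mean())


@dataclass(frozen=True)
class TrendModel:
    """Per-cell linear trend: value ≈ intercept + slope × (year − reference)."""

    cell_id: int
    slope: float
    intercept: float
    reference_year: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("trend coefficients must be finite")


def fit_trend(annual: AnnualIndexSeries, reference_year: int | None = None) -> TrendModel:
    """Ordinary least-squares linear trend of an annual index series."""
    years = annual.years
    if len(years) < 3:
        raise ValueError("need at least 3 years to fit a trend")
    ref = int(reference_year if reference_year is not None else years.min())
    x = years.astype(float) - ref
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, annual.values.to_numpy(), rcond=None)
    return TrendModel(annual.cell_id, float(coef[1]), float(coef[0]), ref)


def extrapolate(
    trend: TrendModel,
    target_year: int,
    *,
    floor: float | None = 0.0,
    cap: float | None = None,
) -> float:
    """Trend-line value at ``target_year``, floored/capped at physical bounds."""
    value = trend.intercept + trend.slope * (target_year - trend.reference_year)
    if floor is not None:
        value = max(floor, value)
    if cap is not None:
        value = min(cap, value)
    return float(value)


@dataclass
class ClimateGrid:
    """Daily climate for all cells of a grid, as (n_cells, n_days) arrays."""

    cell_ids: np.ndarray
    dates: pd.DatetimeIndex
    tmin: np.ndarray
    tmean: np.ndarray
    snow_cm: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids)
        n, d = len(self.cell_ids), len(self.dates)
        for name in ("tmin", "tmean", "snow_cm"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, d):
                raise ValueError(f"{name} must have shape ({n}, {d})")
            setattr(self, name, arr)
        if (self.tmin > self.tmean + 1e-9).any():
            raise ValueError("tmin exceeds tmean somewhere in the grid")
        if (self.snow_cm < 0).any():
            raise ValueError("negative snow depth in the grid")

    def series(self, cell_id: int) -> ClimateSeries:
        (pos,) = np.nonzero(self.cell_ids == cell_id)
        if len(pos) != 1:
            raise KeyError(f"unknown cell {cell_id}")
        i = pos[0]
        frame = pd.DataFrame(
            {"tmin": self.tmin[i], "tmean": self.tmean[i], "snow_cm": self.snow_cm[i]},
            index=self.dates,
        )
        return ClimateSeries(int(cell_id), frame)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (cell_id, date, tmin, tmean, snow_cm)."""
        n, d = self.tmin.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, d),
                "date": np.tile(self.dates.to_numpy(), n),
                "tmin": self.tmin.ravel(),
                "tmean": self.tmean.ravel(),
                "snow_cm": self.snow_cm.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ClimateGrid":
        f = frame.copy()
        f["date"] = pd.DatetimeIndex(f["date"])
        cells = np.sort(f["cell_id"].unique())
        dates = pd.DatetimeIndex(np.sort(f["date"].unique()))
        n, d = len(cells), len(dates)
        if len(f) != n * d:
            counts = f.groupby("cell_id").size()
            bad = counts.index[counts != d].tolist()[:5]
            raise ClimateCoverageError(
                f"ragged climate table: cells {bad} do not cover all {d} dates"
            )
        f = f.sort_values(["cell_id", "date"])
        shape = (n, d)
        return cls(
            cell_ids=cells,
            dates=dates,
            tmin=f["tmin"].to_numpy().reshape(shape),
            tmean=f["tmean"].to_numpy().reshape(shape),
            snow_cm=f["snow_cm"].to_numpy().reshape(shape),
        )

    def _slice(self, dates: pd.DatetimeIndex, what: str) -> slice:
        gaps = dates.difference(self.dates)
        if len(gaps):
            raise ClimateCoverageError(
                f"{len(gaps)} missing days in {what} window starting {gaps[0].date()}"
            )
        a = self.dates.searchsorted(dates[0])
        return slice(a, a + len(dates))


def annual_index_table(
    grid: ClimateGrid,
    winters: range | list[int],
    gs_years: range | list[int],
    spec: WinterSpec | None = None,
) -> pd.DataFrame:
    """Annual WSI and growing-season table for every cell of a climate grid.

    Returns a long table (cell_id, year, wsi, gs); ``wsi`` or ``gs`` is NaN
    for years outside the requested ranges.  Vectorised across cells but
    definitionally identical to the per-cell operations.
    """
    spec = spec or WinterSpec()
    rows: list[pd.DataFrame] = []

    for wy in winters:
        window = spec.window(wy)
        sl = grid._slice(window, f"winter {wy}")
        q = spec.qualifies(grid.tmin[:, sl], grid.snow_cm[:, sl])
        rows.append(
            pd.DataFrame(
                {"cell_id": grid.cell_ids, "year": wy, "wsi": q.sum(axis=1), "gs": np.nan}
            )
        )

    run = 5
    for y in gs_years:
        window = pd.date_range(pd.Timestamp(y, 3, 1), pd.Timestamp(y, 12, 31), freq="D")
        sl = grid._slice(window, f"growing season {y}")
        ok = (grid.tmean[:, sl] >= 5.0).astype(int)
        c = np.cumsum(ok, axis=1)
        c = np.concatenate([np.zeros((ok.shape[0], 1), dtype=int), c], axis=1)
        runsum = c[:, run:] - c[:, :-run]  # windows starting at 0..L-run
        has_start = (runsum == run).any(axis=1)
        start = np.argmax(runsum == run, axis=1)
        aug1 = int(window.searchsorted(pd.Timestamp(y, 8, 1), side="right"))
        cold = grid.tmin[:, sl] <= -2.0
        cold[:, :aug1] = False
        has_end = cold.any(axis=1)
        end = np.where(has_end, np.argmax(cold, axis=1), len(window) - 1)
        gs = np.where(has_start, np.maximum(0, end - start), 0)
        rows.append(
            pd.DataFrame({"cell_id": grid.cell_ids, "year": y, "wsi": np.nan, "gs": gs})
        )

    table = pd.concat(rows, ignore_index=True)
    return (
        table.groupby(["cell_id", "year"], as_index=False)
        .agg({"wsi": "max", "gs": "max"})
        .sort_values(["cell_id", "year"], ignore_index=True)
    )


def annual_series(table: pd.DataFrame, cell_id: int, column: str) -> AnnualIndexSeries:
    """Extract one cell's annual index series from a long (cell_id, year) table."""
    sub = table.loc[table["cell_id"] == cell_id, ["year", column]].dropna()
    return AnnualIndexSeries(
        int(cell_id), pd.Series(sub[column].to_numpy(), index=sub["year"].to_numpy())
    )
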