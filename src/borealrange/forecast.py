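"""Forward projection of decadal distributions under linear climate trends.

Land use and land cover are frozen at the base decade; per-cell linear
trends of the annual winter severity index (WSI) and growing-season length
are extrapolated, and each future decade's climate covariates are cumulative
means from the base years through the decade start — observed annual values
where available, trend-line values beyond (the blended convention, matching
the hindcast's cumulative-mean definition).  Extrapolated WSI is floored at
0 and growing season capped at 366 days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landscape import DecadalLandscape
from .sdm import PredictionGrid, SDMCoefficients, classify, predict_probability

__all__ = ["ForecastScenario", "forecast_decade", "range_change", "RangeChange"]


def _trend_table(trends, cells: np.ndarray) -> pd.DataFrame:
    """Normalise {cell: TrendModel} or a (slope, intercept, ref) frame."""
    if isinstance(trends, dict):
        rows = [
            {"cell_id": c, "slope": t.slope, "intercept": t.intercept,
             "reference_year": t.reference_year}
            for c, t in trends.items()
        ]
        f = pd.DataFrame(rows).set_index("cell_id")
    else:
        f = pd.DataFrame(trends)
        if "cell_id" in f.columns:
            f = f.set_index("cell_id")
    f = f.reindex(cells)
    if f[["slope", "intercept", "reference_year"]].isna().any().any():
        raise ValueError("trend model missing for some grid cells")
    return f


@dataclass
class ForecastScenario:
    """Frozen base landscape plus per-cell climate trends and history.

    ``wsi_annual`` / ``gs_annual`` are the observed long annual tables
    (cell_id, year, value columns 'wsi'/'gs'); trends are per-cell
    :class:`TrendModel` objects (or an equivalent table).
    """

    base_decade: int
    base_landscape: DecadalLandscape
    wsi_annual: pd.DataFrame
    gs_annual: pd.DataFrame
    wsi_trends: pd.DataFrame
    gs_trends: pd.DataFrame
    wsi_base_year: int = 1961
    gs_base_year: int = 1950

    def __post_init__(self) -> None:
        cells = self.base_landscape.cell_ids
        self.wsi_trends = _trend_table(self.wsi_trends, cells)
        self.gs_trends = _trend_table(self.gs_trends, cells)

    def _climate_mean(
        self, annual: pd.DataFrame, column: str, trends: pd.DataFrame,
        base_year: int, end_year: int, cap: float | None,
    ) -> np.ndarray:
        cells = self.base_landscape.cell_ids
        wide = annual.pivot_table(index="cell_id", columns="year", values=column)
        wide = wide.reindex(cells)
        years = np.arange(base_year, end_year + 1)
        observed_years = [y for y in years if y in wide.columns and not wide[y].isna().any()]
        future_years = np.array([y for y in years if y not in observed_years])
        obs = wide[observed_years].to_numpy() if observed_years else np.empty((len(cells), 0))
        if len(future_years):
            gap = future_years[future_years < (max(observed_years) if observed_years else base_year)]
            if observed_years and len(gap):
                raise ValueError(
                    f"{column}: years {gap[:5].tolist()} missing inside the observed record"
                )
            slope = trends["slope"].to_numpy()[:, None]
            intercept = trends["intercept"].to_numpy()[:, None]
            ref = trends["reference_year"].to_numpy()[:, None]
            ext = intercept + slope * (future_years[None, :] - ref)
            ext = np.maximum(0.0, ext)
            if cap is not None:
                ext = np.minimum(cap, ext)
            values = np.concatenate([obs, ext], axis=1)
        else:
            values = obs
        return values.mean(axis=1)


def forecast_decade(
    scenario: ForecastScenario,
    decade: int,
    coef: SDMCoefficients | None = None,
    threshold: float = 0.73,
) -> tuple[PredictionGrid, pd.Series]:
    """Probability grid and presence layer for a future decade.

    Climate covariates are cumulative means from the base years through the
    decade start; the base decade itself reproduces the hindcast exactly
    (only observed years enter the mean).  Land use and cover stay at the
    base decade.
    """
    if decade < scenario.base_decade:
        raise ValueError(f"decade {decade} precedes base decade {scenario.base_decade}")
    wsi = scenario._climate_mean(
        scenario.wsi_annual, "wsi", scenario.wsi_trends,
        scenario.wsi_base_year, decade, cap=None,
    )
    gs = scenario._climate_mean(
        scenario.gs_annual, "gs", scenario.gs_trends,
        scenario.gs_base_year, decade, cap=366.0,
    )
    landscape = scenario.base_landscape.replace(wsi_mean=wsi, gs_mean=gs)
    landscape = DecadalLandscape(decade, landscape.frame)
    grid = predict_probability(landscape, coef)
    return grid, classify(grid, threshold)


@dataclass(frozen=True)
class RangeChange:
    gained_km2: float
    lost_km2: float
    n_gained: int
    n_lost: int

    @property
    def net_km2(self) -> float:
        return self.gained_km2 - self.lost_km2


def range_change(base: pd.Series, future: pd.Series, cell_area_km2: float) -> RangeChange:
    """Area gained (absent→present) and lost (present→absent) between layers."""
    if not base.index.equals(future.index):
        raise ValueError("presence layers are on different grids")
    b = base.astype(bool)
    f = future.astype(bool)
    n_gained = int((~b & f).sum())
    n_lost = int((b & ~f).sum())
    return RangeChange(
        gained_km2=n_gained * cell_area_km2,
        lost_km2=n_lost * cell_area_km2,
        n_gained=n_gained,
        n_lost=n_lost,
    )
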