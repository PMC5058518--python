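"""Synthetic gridded climate, land use, land cover and survey observations.

The generator emulates the statistical structure the analysis assumes,
without any GIS or station inputs: per-cell daily weather whose annual
winter severity index (WSI) and growing-season length follow configured
linear trends with interannual noise; spatially clustered, monotonically
accumulating land-use development (well pads, cut blocks with a fraction of
undated records, persistent agricultural epochs); smooth-ish land-cover
proportions; and Bernoulli presence/absence observations drawn from model
probabilities with optional imperfect detection.

Daily weather is built winter-by-winter and season-by-season so the index
definitions hold exactly: each winter receives a contiguous block of
qualifying days (cold and/or deep snow) whose length is the target WSI, and
each growing season starts at a known date and ends with the first hard
frost after August 1.  This is deliberate plumbing, not meteorology — the
point is that the downstream index, trend and model machinery sees data
with the right marginal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .landscape import GridSpec, LanduseEvents
from .sdm import PredictionGrid

__all__ = [
    "SnowProcess",
    "LanduseGrowth",
    "SyntheticConfig",
    "generate_climate",
    "generate_landcover",
    "generate_landuse_history",
    "sample_observations",
]


@dataclass(frozen=True)
class SnowProcess:
    """Seasonal snow accumulation/melt curve (depth in cm).

    Baseline depth ramps up from the window start to ``base_cm`` in
    mid-winter and melts out by the window end; during the severe sub-block
    the pack deepens to ``peak_cm`` (above the 38 cm index threshold).
    ``severe_fraction`` is the share of severe-winter days whose snow depth
    qualifies on its own.
    """

    base_cm: float = 25.0
    peak_cm: float = 55.0
    severe_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not 0 <= self.severe_fraction <= 1:
            raise ValueError("severe_fraction must lie in [0, 1]")
        if self.base_cm < 0 or self.peak_cm < 0:
            raise ValueError("snow depths must be non-negative")


@dataclass(frozen=True)
class LanduseGrowth:
    """Per-industry development rates and spatial clustering.

    Rates are expected new events per year over the whole grid (Poisson);
    ``clustering`` is the probability a new event lands near one of
    ``n_clusters`` fixed nuclei instead of uniformly at random.
    ``undated_fraction`` of cut blocks lose their year, mirroring real
    cut-block inventories.  Agricultural epochs are {year: fraction of the
    grid's southern rows developed}; epochs persist once on the landscape.
    """

    wells_per_year: float = 3.0
    well_area_km2: float = 1e-4  # 100 m² clearing per pad
    cuts_per_year: float = 2.0
    cut_area_km2: float = 0.5
    undated_fraction: float = 0.3
    ag_epochs: dict = field(default_factory=lambda: {1991: 0.15, 2006: 0.25})
    ag_cell_fraction: float = 0.6
    clustering: float = 0.8
    n_clusters: int = 4

    def __post_init__(self) -> None:
        for name in ("wells_per_year", "cuts_per_year"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("undated_fraction", "clustering", "ag_cell_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    Defaults mirror the boreal study system: ~120 WSI index points and
    ~164 growing-season days on average (the training-data means), winters
    easing by about 1.2 index points per year and growing seasons
    lengthening by 0.15 days per year (within the observed per-cell ranges
    of −2.248…−0.155 and −0.059…+0.375), on a grid of 10 km² cells spanning
    1961 through 2009.
    """

    grid_rows: int = 20
    grid_cols: int = 10
    cell_area_km2: float = 10.0
    start_year: int = 1961
    end_year: int = 2009
    wsi_mean: float = 120.0
    gs_mean: float = 164.0
    climate_trend_wsi: float | np.ndarray = -1.2  # index points / year (scalar or per cell)
    climate_trend_gs: float | np.ndarray = 0.15  # days / year
    wsi_annual_sd: float = 8.0
    gs_annual_sd: float = 4.0
    spatial_sd_wsi: float = 10.0
    spatial_sd_gs: float = 3.0
    daily_noise_sd: float = 1.5
    snow_process: SnowProcess = field(default_factory=SnowProcess)
    landuse_growth: LanduseGrowth = field(default_factory=LanduseGrowth)
    deciduous_mean: float = 0.24
    wetland_mean: float = 0.02
    detection_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one cell")
        if self.end_year < self.start_year:
            raise ValueError(f"empty year range [{self.start_year}, {self.end_year}]")
        if not 0 <= self.detection_prob <= 1:
            raise ValueError("detection_prob must lie in [0, 1]")
        for name in ("wsi_annual_sd", "gs_annual_sd", "daily_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.grid_rows, self.grid_cols, self.cell_area_km2)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)

    def _per_cell(self, value, n: int) -> np.ndarray:
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 0:
            return np.full(n, float(arr))
        if arr.shape != (n,):
            raise ValueError(f"per-cell field must have length {n}")
        return arr


_STREAMS = {"climate": 11, "landcover": 23, "landuse": 37, "observations": 53}


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, _STREAMS[stream]]))


def _smooth_field(rng, grid: GridSpec, sd: float) -> np.ndarray:
    """Spatially correlated per-cell anomaly via one-pass neighbour averaging."""
    raw = rng.normal(0.0, 1.0, size=(grid.rows, grid.cols))
    padded = np.pad(raw, 1, mode="edge")
    sm = (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2]
        + padded[1:-1, 2:] + raw
    ) / 5.0
    sm = sm / sm.std() if sm.std() > 0 else sm
    return (sm * sd).ravel()


def generate_climate(config: SyntheticConfig) -> ClimateGrid:
    """Daily per-cell weather whose annual indices follow the configured trends.

    Returns a :class:`ClimateGrid` covering Jan 1 of the start year through
    Dec 31 of the end year; winters are computable for start..end−1 (each
    needs the following April) and growing seasons for every year.
    """
    rng = _rng(config, "climate")
    grid = config.grid
    n = grid.n_cells
    dates = pd.date_range(
        pd.Timestamp(config.start_year, 1, 1),
        pd.Timestamp(config.end_year, 12, 31),
        freq="D",
    )
    nd = len(dates)

    base_wsi = config.wsi_mean + _smooth_field(rng, grid, config.spatial_sd_wsi)
    base_gs = config.gs_mean + _smooth_field(rng, grid, config.spatial_sd_gs)
    trend_wsi = config._per_cell(config.climate_trend_wsi, n)
    trend_gs = config._per_cell(config.climate_trend_gs, n)

    noise_sd = config.daily_noise_sd

    def jitter(shape, lo=None, hi=None):
        x = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else np.zeros(shape)
        return np.clip(x, lo, hi)

    # Mild baseline: never qualifies for either index.
    tmin = np.full((n, nd), -6.0) + jitter((n, nd), -8.0, 8.0)
    tmean = tmin + 6.0
    snow = np.zeros((n, nd))

    loc = dates.searchsorted  # date -> column index
    snow_p = config.snow_process

    # --- winters: contiguous qualifying block per winter, length = target WSI
    for wy in range(config.start_year, config.end_year):
        a = loc(pd.Timestamp(wy, 11, 1))
        b = loc(pd.Timestamp(wy + 1, 4, 30)) + 1
        L = b - a
        eps = rng.normal(0.0, config.wsi_annual_sd, size=n) if config.wsi_annual_sd else 0.0
        target = np.clip(
            np.rint(base_wsi + trend_wsi * (wy - config.start_year) + eps), 0, L
        ).astype(int)
        # seasonal baseline snow, kept below the 38 cm threshold
        ramp = 1.0 - np.abs(np.linspace(-1.0, 1.0, L))
        snow[:, a:b] = np.minimum(snow_p.base_cm, 37.0) * ramp
        mid = L // 2
        start = np.clip(mid - target // 2, 0, np.maximum(0, L - target))
        for i in range(n):
            q = target[i]
            if q == 0:
                continue
            s = a + start[i]
            tmin[i, s : s + q] = -25.0 + jitter(q, -12.0, 6.9)  # stays < −17.7
            tmean[i, s : s + q] = tmin[i, s : s + q] + 6.0
            k = int(round(snow_p.severe_fraction * q))
            if k:
                off = s + (q - k) // 2
                snow[i, off : off + k] = max(snow_p.peak_cm, 39.0) + jitter(k, -15.0, 15.0)

    # --- growing seasons: known start, first frost after Aug 1 at start+length
    for y in range(config.start_year, config.end_year + 1):
        mar1 = loc(pd.Timestamp(y, 3, 1))
        may1 = loc(pd.Timestamp(y, 5, 1))
        nov1 = loc(pd.Timestamp(y, 11, 1))
        eps = rng.normal(0.0, config.gs_annual_sd, size=n) if config.gs_annual_sd else 0.0
        # season must end before Nov 1 so the frost never collides with the
        # next winter's severity block
        length = np.clip(
            np.rint(base_gs + trend_gs * (y - config.start_year) + eps),
            100,
            nov1 - may1 - 2,
        ).astype(int)
        for i in range(n):
            s = may1
            e = s + length[i]  # first frost day; season = [s, e), length days
            tmean[i, s:e] = 12.0 + jitter(e - s, -6.4, 15.0)  # ≥ 5.6 °C
            tmin[i, s:e] = np.minimum(tmean[i, s:e] - 4.0, 4.0)
            tmin[i, s:e] = np.maximum(tmin[i, s:e], -1.9)  # no frost before e
            tmean[i, s:e] = np.maximum(tmean[i, s:e], tmin[i, s:e])
            tmin[i, e] = -4.0 + (jitter(1, -4.0, 1.9)[0] if noise_sd else 0.0)
            tmean[i, e] = tmin[i, e] + 6.0
            # shoulder seasons stay below the 5 °C onset and above −2 °C frost
            tmean[i, mar1:s] = np.minimum(tmean[i, mar1:s], 4.0)
            tmin[i, mar1:s] = np.minimum(tmin[i, mar1:s], tmean[i, mar1:s] - 2.0)
            post = slice(e + 1, nov1)
            if post.stop > post.start:
                tmin[i, post] = -5.0 + (
                    jitter(post.stop - post.start, -5.0, 2.0) if noise_sd else 0.0
                )
                tmean[i, post] = tmin[i, post] + 6.0

    tmean = np.maximum(tmean, tmin)
    return ClimateGrid(grid.cell_ids, dates, tmin, tmean, snow)


def generate_landcover(config: SyntheticConfig) -> pd.DataFrame:
    """Per-cell deciduous and wetland proportions (cell_id, prop_deciduous, prop_wetland)."""
    rng = _rng(config, "landcover")
    grid = config.grid
    dec = np.clip(
        config.deciduous_mean + _smooth_field(rng, grid, 0.15), 0.0, 0.9
    )
    wet = np.clip(rng.exponential(config.wetland_mean, size=grid.n_cells), 0.0, 0.13)
    return pd.DataFrame(
        {"cell_id": grid.cell_ids, "prop_deciduous": dec, "prop_wetland": wet}
    )


def _place_events(rng, grid: GridSpec, n_events: int, nuclei, clustering: float) -> np.ndarray:
    """Cell ids for new events: clustered around nuclei or uniform."""
    if n_events == 0:
        return np.empty(0, dtype=int)
    use_cluster = rng.random(n_events) < clustering
    cells = np.empty(n_events, dtype=int)
    uniform = ~use_cluster
    cells[uniform] = rng.integers(0, grid.n_cells, size=int(uniform.sum()))
    k = int(use_cluster.sum())
    if k:
        centers = nuclei[rng.integers(0, len(nuclei), size=k)]
        rows = np.clip(
            centers // grid.cols + np.rint(rng.normal(0, 1.2, k)), 0, grid.rows - 1
        )
        cols = np.clip(
            centers % grid.cols + np.rint(rng.normal(0, 1.2, k)), 0, grid.cols - 1
        )
        cells[use_cluster] = (rows * grid.cols + cols).astype(int)
    return cells


def generate_landuse_history(config: SyntheticConfig) -> LanduseEvents:
    """Dated development events with clustered growth and persistent agriculture."""
    rng = _rng(config, "landuse")
    grid = config.grid
    growth = config.landuse_growth
    nuclei = rng.integers(0, grid.n_cells, size=max(1, growth.n_clusters))

    wells_rows, cuts_rows = [], []
    for year in config.years:
        for rate, area, rows_out in (
            (growth.wells_per_year, growth.well_area_km2, wells_rows),
            (growth.cuts_per_year, growth.cut_area_km2, cuts_rows),
        ):
            n_new = rng.poisson(rate) if rate > 0 else 0
            for cell in _place_events(rng, grid, n_new, nuclei, growth.clustering):
                rows_out.append({"cell_id": int(cell), "year": int(year), "area_km2": area})

    wells = pd.DataFrame(wells_rows, columns=["cell_id", "year", "area_km2"])
    cuts = pd.DataFrame(cuts_rows, columns=["cell_id", "year", "area_km2"])
    if len(cuts) and growth.undated_fraction > 0:
        undated = rng.random(len(cuts)) < growth.undated_fraction
        cuts.loc[undated, "year"] = np.nan

    ag_rows = []
    for year in sorted(growth.ag_epochs):
        frac = growth.ag_epochs[year]
        if not config.start_year <= year <= config.end_year or frac <= 0:
            continue
        n_rows = int(round(frac * grid.rows))
        south = np.arange(grid.rows - n_rows, grid.rows)
        for r in south:
            for c in range(grid.cols):
                ag_rows.append(
                    {
                        "cell_id": int(r * grid.cols + c),
                        "year": int(year),
                        "area_km2": growth.ag_cell_fraction * grid.cell_area_km2,
                    }
                )
    agriculture = pd.DataFrame(ag_rows, columns=["cell_id", "year", "area_km2"])
    return LanduseEvents(wells=wells, cutblocks=cuts, agriculture=agriculture)


def sample_observations(
    probabilities: PredictionGrid,
    n_sites: int,
    detection_prob: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence/absence observations at cells sampled without replacement.

    Each sampled cell records presence with probability p × detection_prob
    (imperfect detection thins true presences into false absences).
    """
    if not 0 <= detection_prob <= 1:
        raise ValueError("detection_prob must lie in [0, 1]")
    cells = probabilities.frame.index.to_numpy()
    if n_sites > len(cells):
        raise ValueError(f"n_sites={n_sites} exceeds the {len(cells)} grid cells")
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(cells), size=n_sites, replace=False)
    p = probabilities.probability.to_numpy()[chosen] * detection_prob
    presence = rng.random(n_sites) < p
    return pd.DataFrame(
        {"cell_id": cells[chosen], "presence": presence.astype(int), "p_true": p}
    )
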