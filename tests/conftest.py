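import numpy as np
import pandas as pd
import pytest

from borealrange.climate import ClimateSeries
from borealrange.landscape import DecadalLandscape
from borealrange.synthetic import SyntheticConfig, generate_climate


def make_series(
    start="1979-07-01",
    end="1981-12-31",
    tmin=-6.0,
    tmean=0.0,
    snow_cm=0.0,
    cell_id=0,
) -> ClimateSeries:
    """Constant daily series; tests overwrite the days they care about."""
    dates = pd.date_range(start, end, freq="D")
    frame = pd.DataFrame(
        {
            "tmin": np.full(len(dates), float(tmin)),
            "tmean": np.full(len(dates), float(tmean)),
            "snow_cm": np.full(len(dates), float(snow_cm)),
        },
        index=dates,
    )
    return ClimateSeries(cell_id, frame)


def make_landscape(
    decade=2000,
    n_cells=4,
    prop_deciduous=0.24,
    prop_wetland=0.02,
    prop_footprint=0.12,
    wsi_mean=119.26,
    gs_mean=163.70,
) -> DecadalLandscape:
    """Landscape with constant covariates (defaults: training-data means)."""
    idx = pd.Index(np.arange(n_cells), name="cell_id")

    def col(v):
        return np.broadcast_to(np.asarray(v, dtype=float), (n_cells,)).copy()

    frame = pd.DataFrame(
        {
            "prop_deciduous": col(prop_deciduous),
            "prop_wetland": col(prop_wetland),
            "prop_footprint": col(prop_footprint),
            "wsi_mean": col(wsi_mean),
            "gs_mean": col(gs_mean),
        },
        index=idx,
    )
    return DecadalLandscape(decade, frame)


@pytest.fixture(scope="session")
def small_climate_config() -> SyntheticConfig:
    return SyntheticConfig(grid_rows=3, grid_cols=2, start_year=1961, end_year=1985, seed=7)


@pytest.fixture(scope="session")
def small_climate(small_climate_config):
    return generate_climate(small_climate_config)
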