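"""Winter severity, growing season, cumulative means, trends."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from borealrange.climate import (
    AnnualIndexSeries,
    ClimateCoverageError,
    TrendModel,
    annual_index_table,
    annual_series,
    compute_growing_season,
    compute_wsi,
    cumulative_mean,
    extrapolate,
    fit_trend,
)

from conftest import make_series


class TestWSI:
    def test_every_day_qualifies_gives_window_length(self):
        # 1979-80 winter has a leap February -> 182-day window
        s = make_series(tmin=-30.0, tmean=-24.0, snow_cm=50.0)
        assert compute_wsi(s, 1979) == 182
        assert compute_wsi(s, 1980) == 181

    def test_no_day_qualifies_gives_zero(self):
        s = make_series(tmin=0.0, tmean=3.0, snow_cm=0.0)
        assert compute_wsi(s, 1980) == 0

    def test_cold_and_snow_days_counted_once(self):
        # 40 cold-only + 30 snow-only + 10 both -> 80 qualifying days
        s = make_series(tmin=-5.0, tmean=0.0, snow_cm=0.0)
        days = pd.date_range("1980-11-01", "1981-04-30", freq="D")
        f = s.frame
        f.loc[days[:40], "tmin"] = -20.0
        f.loc[days[40:70], "snow_cm"] = 45.0
        f.loc[days[70:80], "tmin"] = -25.0
        f.loc[days[70:80], "snow_cm"] = 60.0
        brute = int(
            ((f.loc[days, "tmin"] < -17.7) | (f.loc[days, "snow_cm"] > 38.0)).sum()
        )
        assert brute == 80
        assert compute_wsi(s, 1980) == 80

    def test_thresholds_are_strict(self):
        s = make_series(tmin=-17.7, tmean=-10.0, snow_cm=38.0)
        assert compute_wsi(s, 1980) == 0

    def test_missing_days_raise_listing_gaps(self):
        s = make_series()
        s.frame = s.frame.drop(pd.Timestamp("1981-01-15"))
        with pytest.raises(ClimateCoverageError, match="1981-01-15"):
            compute_wsi(s, 1980)

    @settings(derandomize=True, max_examples=25)
    @given(
        drop=st.floats(min_value=0.0, max_value=30.0),
        day=st.integers(min_value=0, max_value=180),
    )
    def test_monotone_under_colder_perturbation(self, drop, day):
        s = make_series(tmin=-16.0, tmean=-10.0, snow_cm=30.0)
        base = compute_wsi(s, 1980)
        target = pd.date_range("1980-11-01", "1981-04-30", freq="D")[day]
        s.frame.loc[target, "tmin"] -= drop
        assert compute_wsi(s, 1980) >= base


class TestGrowingSeason:
    def test_no_warm_run_gives_zero(self):
        s = make_series(tmin=-6.0, tmean=2.0)
        assert compute_growing_season(s, 1980) == 0

    def test_constructed_season_length_by_calendar(self):
        # warm run starts Apr 10; first frost after Aug 1 on Sep 30
        # -> Apr 10..Sep 30 is 173 days by calendar enumeration
        s = make_series(tmin=3.0, tmean=4.0)
        f = s.frame
        warm = pd.date_range("1980-04-10", "1980-09-29", freq="D")
        f.loc[warm, "tmean"] = 10.0
        f.loc[warm, "tmin"] = 5.0
        f.loc[pd.Timestamp("1980-09-30"), "tmin"] = -3.0
        assert (pd.Timestamp("1980-09-30") - pd.Timestamp("1980-04-10")).days == 173
        assert compute_growing_season(s, 1980) == 173

    def test_shifting_start_one_day_shortens_by_one(self):
        def season(start):
            s = make_series(tmin=3.0, tmean=4.0)
            warm = pd.date_range(start, "1980-09-29", freq="D")
            s.frame.loc[warm, "tmean"] = 10.0
            s.frame.loc[warm, "tmin"] = 5.0
            s.frame.loc[pd.Timestamp("1980-09-30"), "tmin"] = -3.0
            return compute_growing_season(s, 1980)

        assert season("1980-04-11") == season("1980-04-10") - 1

    def test_no_frost_ends_at_dec31(self):
        s = make_series(tmin=0.0, tmean=8.0)
        # start is March 1 itself; no tmin <= -2 ever
        assert compute_growing_season(s, 1980) == (
            pd.Timestamp("1980-12-31") - pd.Timestamp("1980-03-01")
        ).days

    def test_frost_before_august_does_not_end_season(self):
        s = make_series(tmin=0.0, tmean=8.0)
        s.frame.loc[pd.Timestamp("1980-06-15"), "tmin"] = -10.0
        s.frame.loc[pd.Timestamp("1980-10-01"), "tmin"] = -3.0
        assert compute_growing_season(s, 1980) == (
            pd.Timestamp("1980-10-01") - pd.Timestamp("1980-03-01")
        ).days

    def test_weather_outside_window_is_irrelevant(self):
        s1 = make_series(tmin=0.0, tmean=8.0)
        s2 = make_series(tmin=0.0, tmean=8.0)
        s2.frame.loc[: pd.Timestamp("1980-02-28"), ["tmin", "tmean"]] = -30.0
        s2.frame.loc[pd.Timestamp("1981-01-01") :, ["tmin", "tmean"]] = -30.0
        s1f = compute_growing_season(s1, 1980)
        assert compute_growing_season(s2, 1980) == s1f


class TestCumulativeMean:
    def test_single_year(self):
        a = AnnualIndexSeries(0, pd.Series({1970: 42.0}))
        assert cumulative_mean(a, 1970, 1970) == 42.0

    def test_three_year_arithmetic(self):
        a = AnnualIndexSeries(0, pd.Series({1970: 100.0, 1971: 110.0, 1972: 120.0}))
        assert cumulative_mean(a, 1970, 1972) == pytest.approx(110.0)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        years = np.arange(1961, 2003)
        vals = rng.uniform(60, 190, len(years))
        a = AnnualIndexSeries(0, pd.Series(vals, index=years))
        assert cumulative_mean(a, 1961, 2002) == pytest.approx(vals.sum() / len(vals), abs=1e-12)

    def test_missing_year_raises(self):
        a = AnnualIndexSeries(0, pd.Series({1970: 1.0, 1972: 2.0}))
        with pytest.raises(ClimateCoverageError, match="1971"):
            cumulative_mean(a, 1970, 1972)

    def test_adding_a_block_moves_mean_toward_block(self):
        a = AnnualIndexSeries(0, pd.Series(np.r_[np.full(10, 100.0), np.full(10, 80.0)],
                                           index=np.arange(1961, 1981)))
        m1 = cumulative_mean(a, 1961, 1970)
        m2 = cumulative_mean(a, 1961, 1980)
        assert 80.0 < m2 < m1


class TestTrend:
    def test_exact_linear_recovery(self):
        years = np.arange(1961, 2003)
        a = AnnualIndexSeries(0, pd.Series(200.0 - 1.5 * (years - 1961), index=years))
        t = fit_trend(a)
        assert t.slope == pytest.approx(-1.5, abs=1e-12)
        assert t.intercept == pytest.approx(200.0, abs=1e-9)

    def test_constant_gives_zero_slope(self):
        a = AnnualIndexSeries(0, pd.Series(7.0, index=np.arange(1990, 2000)))
        assert fit_trend(a).slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        years = np.arange(1961, 2003)
        vals = 120 - 0.8 * (years - 1961) + rng.normal(0, 5, len(years))
        a = AnnualIndexSeries(0, pd.Series(vals, index=years))
        t = fit_trend(a)
        # closed-form normal equations
        x = years - 1961.0
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (vals - vals.mean())).sum() / sxx
        intercept = vals.mean() - slope * x.mean()
        assert t.slope == pytest.approx(slope, abs=1e-9)
        assert t.intercept == pytest.approx(intercept, abs=1e-9)

    def test_too_few_years_raises(self):
        a = AnnualIndexSeries(0, pd.Series({1990: 1.0, 1991: 2.0}))
        with pytest.raises(ValueError, match="3 years"):
            fit_trend(a)

    def test_extrapolate_floors_at_zero(self):
        t = TrendModel(0, slope=-2.248, intercept=100.0, reference_year=2000)
        assert extrapolate(t, 2050) == 0.0  # 100 - 112.4 < 0
        assert extrapolate(t, 2000) == 100.0

    def test_extrapolate_zero_slope_is_intercept(self):
        t = TrendModel(0, slope=0.0, intercept=55.0, reference_year=1990)
        for y in (1990, 2010, 2100):
            assert extrapolate(t, y) == 55.0


class TestGridTable:
    def test_vectorised_table_matches_per_cell_ops(self, small_climate):
        table = annual_index_table(
            small_climate, winters=range(1965, 1975), gs_years=range(1965, 1975)
        )
        for cell in (0, 5):
            s = small_climate.series(cell)
            for year in (1965, 1970, 1974):
                row = table[(table.cell_id == cell) & (table.year == year)]
                assert row.wsi.iloc[0] == compute_wsi(s, year)
                assert row.gs.iloc[0] == compute_growing_season(s, year)

    def test_annual_series_roundtrip(self, small_climate):
        table = annual_index_table(
            small_climate, winters=range(1965, 1970), gs_years=range(1965, 1970)
        )
        s = annual_series(table.dropna(subset=["wsi"]), 3, "wsi")
        assert list(s.years) == list(range(1965, 1970))
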