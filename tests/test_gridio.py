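"""Reading, regridding, calendar standardization and outlier screening."""

import numpy as np
import pytest

from climautocorr import calendars as cal
from climautocorr.exceptions import FormatError
from climautocorr.gridio import (
    GriddedTemperature,
    normalize_longitudes,
    read_gridded_temperature,
    regrid_to_one_degree,
    screen_outliers,
    standardize_calendar,
)

from conftest import make_grid


class TestCalendars:
    def test_leap_rules(self):
        assert cal.is_leap(2000) and cal.is_leap(2004)
        assert not cal.is_leap(1900) and not cal.is_leap(2001)

    def test_year_lengths(self):
        assert cal.year_length(2000, "standard") == 366
        assert cal.year_length(2000, "noleap") == 365
        assert cal.year_length(2000, "360_day") == 360

    def test_date_range_crosses_year(self):
        dates = cal.date_range((1999, 12, 30), 4, "standard")
        assert [tuple(d) for d in dates] == [
            (1999, 12, 30), (1999, 12, 31), (2000, 1, 1), (2000, 1, 2)]

    def test_decimal_year(self):
        dates = np.array([[2001, 1, 1], [2001, 7, 2]])
        dec = cal.decimal_year(dates, "standard")
        assert dec[0] == 2001.0
        assert dec[1] == pytest.approx(2001.0 + 182 / 365)

    def test_unknown_calendar_rejected(self):
        with pytest.raises(FormatError):
            cal.canonical_calendar("julian-ish")


class TestContainer:
    def test_longitudes_normalized(self):
        assert normalize_longitudes([350.0, 180.0, 10.0]).tolist() == [-10.0, -180.0, 10.0]

    def test_duplicate_timestamps_rejected(self):
        dates = np.array([[2000, 1, 1], [2000, 1, 1]])
        with pytest.raises(ValueError, match="duplicate"):
            GriddedTemperature(lat=[0.0], lon=[0.0], dates=dates, values=np.zeros((2, 1, 1)))

    def test_netcdf_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        data = make_grid(rng.normal(10, 5, (40, 3, 4)), lat=[-1, 0, 1], lon=[10, 11, 12, 13],
                         calendar=cal.NOLEAP, start=(1999, 12, 20))
        path = tmp_path / "t.nc"
        data.to_netcdf(path)
        back = read_gridded_temperature(path)
        assert back.calendar == cal.NOLEAP
        np.testing.assert_array_equal(back.lat, data.lat)
        np.testing.assert_array_equal(back.lon, data.lon)
        np.testing.assert_array_equal(back.dates, data.dates)
        np.testing.assert_allclose(back.values, data.values, rtol=0, atol=1e-12)

    def test_read_converts_kelvin_and_fill(self, tmp_path):
        data = make_grid(np.full((20, 2, 2), 300.0))
        ds = data.to_xarray()
        ds["tas"].attrs["units"] = "K"
        vals = ds["tas"].values
        vals[0, 0, 0] = -9999.0
        ds["tas"].values = vals
        ds["tas"].attrs["_FillValue"] = -9999.0
        path = tmp_path / "k.nc"
        ds.to_netcdf(path, engine="scipy")
        back = read_gridded_temperature(path)
        assert back.values[0, 0, 1] == pytest.approx(26.85)
        assert np.isnan(back.values[0, 0, 0])

    def test_read_rejects_unknown_units(self, tmp_path):
        data = make_grid(np.zeros((20, 2, 2)))
        ds = data.to_xarray()
        ds["tas"].attrs["units"] = "furlongs"
        path = tmp_path / "u.nc"
        ds.to_netcdf(path, engine="scipy")
        with pytest.raises(FormatError, match="units"):
            read_gridded_temperature(path)


class TestRegrid:
    def test_constant_field_preserved(self):
        data = make_grid(np.full((2, 5, 5), 10.0),
                         lat=np.arange(-4, 5, 2.0), lon=np.arange(0, 9, 2.0))
        out = regrid_to_one_degree(data)
        assert out.lat.tolist() == list(range(-4, 5))
        np.testing.assert_allclose(out.values, 10.0)

    def test_bilinear_reproduces_planes(self):
        lon = np.arange(0, 9, 2.0)
        lat = np.arange(-4, 5, 2.0)
        field = np.tile(3.0 * lon + 1.0, (len(lat), 1))[None, :, :]
        out = regrid_to_one_degree(make_grid(field, lat=lat, lon=lon))
        expected = np.tile(3.0 * out.lon + 1.0, (len(out.lat), 1))
        np.testing.assert_allclose(out.values[0], expected, atol=1e-9)

    def test_all_missing_stays_missing(self):
        data = make_grid(np.full((2, 4, 4), np.nan), lat=np.arange(-3, 4, 2.0), lon=np.arange(0, 7, 2.0))
        out = regrid_to_one_degree(data)
        assert np.isnan(out.values).all()

    def test_partial_stencil_renormalized(self):
        # one missing corner must not poison the average of the other three
        lat = np.array([0.0, 2.0])
        lon = np.array([0.0, 2.0])
        vals = np.array([[[1.0, 1.0], [1.0, np.nan]]])
        out = regrid_to_one_degree(make_grid(vals, lat=lat, lon=lon))
        i = out.lat.tolist().index(1)
        j = out.lon.tolist().index(1)
        assert out.values[0, i, j] == pytest.approx(1.0)


class TestCalendarStandardization:
    def test_noleap_gains_missing_feb29(self):
        data = make_grid(np.arange(365, dtype=float).reshape(-1, 1, 1),
                         start=(2000, 1, 1), calendar=cal.NOLEAP)
        out = standardize_calendar(data)
        assert out.calendar == cal.STANDARD
        assert out.n_time == 366
        feb29 = [i for i, d in enumerate(out.dates) if tuple(d)[1:] == (2, 29)]
        assert len(feb29) == 1
        assert np.isnan(out.values[feb29[0]])
        others = np.delete(out.values[:, 0, 0], feb29[0])
        np.testing.assert_array_equal(others, data.values[:, 0, 0])

    def test_standard_identity(self):
        data = make_grid(np.zeros((30, 1, 1)))
        assert standardize_calendar(data) is data

    def test_360_day_no_duplicates(self):
        data = make_grid(np.arange(360, dtype=float).reshape(-1, 1, 1),
                         start=(2001, 1, 1), calendar=cal.CAL_360)
        out = standardize_calendar(data)
        assert out.calendar == cal.STANDARD
        assert out.n_time == 365
        keys = [tuple(d) for d in out.dates]
        assert len(set(keys)) == len(keys)
        # every non-inserted value appears unchanged
        kept = out.values[np.isfinite(out.values[:, 0, 0]), 0, 0]
        assert set(kept).issubset(set(data.values[:, 0, 0]))


class TestOutliers:
    def test_boundary_behavior(self):
        vals = np.array([60.1, 60.0, -89.0, np.nan]).reshape(-1, 1, 1)
        out = screen_outliers(make_grid(vals))
        assert np.isnan(out.values[0, 0, 0])
        assert out.values[1, 0, 0] == 60.0
        assert out.values[2, 0, 0] == -89.0
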