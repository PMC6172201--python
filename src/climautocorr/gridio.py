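"""Gridded daily temperature: container, NetCDF I/O, and standardization.

Model output arrives on heterogeneous grids and calendars.  Before any
autocorrelation analysis every dataset is brought onto a common footing:
a regular 1°x1° latitude-longitude grid, the real (leap-year aware)
calendar, and physically plausible values (anything above 60 °C is
treated as a data artifact and masked).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

from . import calendars as cal
from .exceptions import FormatError

log = logging.getLogger(__name__)

_TEMP_NAMES = ("tas", "temperature", "temp", "t2m", "air_temperature")
_KELVIN_UNITS = {"k", "kelvin", "degk", "deg_k"}
_CELSIUS_UNITS = {"degc", "deg_c", "celsius", "c", "degrees_celsius", "°c"}


def normalize_longitudes(lon: np.ndarray) -> np.ndarray:
    """Map longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class GriddedTemperature:
    """Daily temperature values (°C) on a regular lat-lon grid.

    Parameters
    ----------
    lat, lon : 1-D arrays of cell-center coordinates (degrees).  Latitude
        must be strictly monotone; longitudes are normalized to [-180, 180).
    dates : (n_time, 3) int array of (year, month, day) under `calendar`.
    values : (n_time, n_lat, n_lon) float array, NaN marks missing.
    calendar : one of "standard", "noleap", "360_day".
    """

    lat: np.ndarray
    lon: np.ndarray
    dates: np.ndarray
    values: np.ndarray
    calendar: str = cal.STANDARD
    name: str = field(default="tas")

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = normalize_longitudes(self.lon)
        self.dates = np.asarray(self.dates, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.calendar = cal.canonical_calendar(self.calendar)
        if np.any(np.abs(self.lat) > 90):
            raise ValueError("latitudes must lie in [-90, 90]")
        dlat = np.diff(self.lat)
        if len(dlat) and not (np.all(dlat > 0) or np.all(dlat < 0)):
            raise ValueError("latitude must be strictly monotone")
        if self.values.shape != (len(self.dates), len(self.lat), len(self.lon)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(time={len(self.dates)}, lat={len(self.lat)}, lon={len(self.lon)})"
            )
        keys = [tuple(d) for d in self.dates]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate timestamps")
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("time must be strictly increasing")

    # -- time helpers -------------------------------------------------
    @property
    def n_time(self) -> int:
        return len(self.dates)

    @property
    def years(self) -> np.ndarray:
        return self.dates[:, 0]

    def decimal_year(self) -> np.ndarray:
        return cal.decimal_year(self.dates, self.calendar)

    def day_of_year(self) -> np.ndarray:
        return cal.day_of_year(self.dates, self.calendar)

    # -- xarray / NetCDF ----------------------------------------------
    def to_xarray(self) -> xr.Dataset:
        origin = tuple(int(v) for v in self.dates[0])
        offsets = np.array(
            [cal.date_span_days(origin, tuple(int(v) for v in d), self.calendar) - 1 for d in self.dates],
            dtype=np.int32,
        )
        ds = xr.Dataset(
            {self.name: (("time", "lat", "lon"), self.values)},
            coords={"time": ("time", offsets), "lat": ("lat", self.lat), "lon": ("lon", self.lon)},
        )
        ds[self.name].attrs.update(units="degC", long_name="surface air temperature")
        ds["time"].attrs.update(
            units=f"days since {origin[0]:04d}-{origin[1]:02d}-{origin[2]:02d}",
            calendar=self.calendar,
        )
        ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
        ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
        return ds

    def to_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")


def _parse_time_axis(ds: xr.Dataset) -> tuple[np.ndarray, str]:
    time = ds["time"]
    units = str(time.attrs.get("units", ""))
    calendar = cal.canonical_calendar(time.attrs.get("calendar", "standard"))
    if not units.lower().startswith("days since"):
        raise FormatError(f"unsupported time units {units!r} (need 'days since ...')")
    origin_str = units.split("since", 1)[1].strip().split()[0]
    parts = origin_str.split("-")
    origin = (int(parts[0]), int(parts[1]), int(parts[2]))
    offsets = np.asarray(time.values)
    if not np.allclose(offsets, np.round(offsets)):
        raise FormatError("time axis is not daily (non-integer day offsets)")
    offsets = np.round(offsets).astype(np.int64)
    seq = cal.date_range(origin, int(offsets.max()) + 1, calendar)
    return seq[offsets], calendar


def read_gridded_temperature(path) -> GriddedTemperature:
    """Read a CF-style NetCDF file of daily temperature.

    Values stored in Kelvin are converted to °C; declared fill values
    become missing (NaN); the file's calendar tag is preserved.
    """
    with xr.open_dataset(path, decode_times=False, engine="scipy") as ds:
        var_name = next((n for n in _TEMP_NAMES if n in ds.data_vars), None)
        if var_name is None:
            raise FormatError(f"no recognized temperature variable in {path} (looked for {_TEMP_NAMES})")
        var = ds[var_name]
        for coord in ("time", "lat", "lon"):
            if coord not in ds.variables:
                for alias in ("latitude", "longitude"):
                    if alias.startswith(coord) and alias in ds.variables:
                        ds = ds.rename({alias: coord})
                        var = ds[var_name]
                        break
                else:
                    raise FormatError(f"missing coordinate {coord!r} in {path}")
        units = str(var.attrs.get("units", "")).lower()
        values = np.asarray(var.transpose("time", "lat", "lon").values, dtype=float)
        if units in _KELVIN_UNITS:
            values = values - 273.15
        elif units not in _CELSIUS_UNITS:
            raise FormatError(f"unrecognized temperature units {var.attrs.get('units')!r}")
        dates, calendar = _parse_time_axis(ds)
        return GriddedTemperature(
            lat=np.asarray(ds["lat"].values, dtype=float),
            lon=np.asarray(ds["lon"].values, dtype=float),
            dates=dates,
            values=values,
            calendar=calendar,
            name=var_name,
        )


# -- standardization --------------------------------------------------

def regrid_to_one_degree(data: GriddedTemperature) -> GriddedTemperature:
    """Bilinear interpolation onto the integer-centered 1° x 1° grid.

    The target grid covers the integer latitudes/longitudes inside the
    source domain (no extrapolation).  Interpolation is NaN-aware: a
    target cell is missing only when all source cells in its 2x2 stencil
    are missing; otherwise the weights of the valid corners are
    renormalized.
    """
    lat_s = data.lat if data.lat[0] < data.lat[-1] else data.lat[::-1]
    flip = data.lat[0] > data.lat[-1]
    vals = data.values[:, ::-1, :] if flip else data.values
    order = np.argsort(data.lon)
    lon_s = data.lon[order]
    vals = vals[:, :, order]

    lat_t = np.arange(np.ceil(lat_s[0]), np.floor(lat_s[-1]) + 1)
    lon_t = np.arange(np.ceil(lon_s[0]), np.floor(lon_s[-1]) + 1)
    if len(lat_t) == 0 or len(lon_t) == 0:
        raise ValueError("source domain contains no integer grid points")

    def _bracket(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hi = np.searchsorted(src, tgt, side="left").clip(1, len(src) - 1)
        lo = hi - 1
        w = (tgt - src[lo]) / (src[hi] - src[lo])
        return lo, w.clip(0.0, 1.0)

    ilat, wlat = _bracket(lat_s, lat_t)
    ilon, wlon = _bracket(lon_s, lon_t)

    out = np.zeros((data.n_time, len(lat_t), len(lon_t)))
    wsum = np.zeros_like(out)
    for dy in (0, 1):
        for dx in (0, 1):
            corner = vals[:, ilat + dy][:, :, ilon + dx]
            w = (wlat if dy else 1 - wlat)[:, None] * (wlon if dx else 1 - wlon)[None, :]
            valid = np.isfinite(corner)
            out += np.where(valid, corner, 0.0) * w
            wsum += valid * w
    with np.errstate(invalid="ignore"):
        out = np.where(wsum > 0, out / np.where(wsum > 0, wsum, 1.0), np.nan)
    return replace(data, lat=lat_t, lon=lon_t, values=out)


def standardize_calendar(data: GriddedTemperature) -> GriddedTemperature:
    """Re-express the time axis on the real (standard) calendar.

    noleap input gains a missing Feb 29 in leap years (to be filled later
    by temporal interpolation).  360_day input is mapped proportionally
    within each month; real dates with no source day become missing.
    Non-inserted values are never altered.
    """
    if data.calendar == cal.STANDARD:
        return data
    start = tuple(int(v) for v in data.dates[0])
    end = tuple(int(v) for v in data.dates[-1])
    if data.calendar == cal.NOLEAP:
        n = cal.date_span_days(start, end, cal.STANDARD)
        new_dates = cal.date_range(start, n, cal.STANDARD)
        index = {(y, m, d): i for i, (y, m, d) in enumerate(map(tuple, new_dates))}
        new_vals = np.full((n,) + data.values.shape[1:], np.nan)
        for src_i, (y, m, d) in enumerate(map(tuple, data.dates)):
            new_vals[index[(y, m, d)]] = data.values[src_i]
        return replace(data, dates=new_dates, values=new_vals, calendar=cal.STANDARD)

    # 360_day: source day d (1..30) of a month with L real days maps to
    # real day floor((d-1) * L / 30) + 1; first write wins, unmapped real
    # days stay missing.
    tgt_start = (start[0], start[1], 1)
    last_len = cal.month_lengths(end[0], cal.STANDARD)[end[1] - 1]
    tgt_end = (end[0], end[1], last_len)
    n = cal.date_span_days(tgt_start, tgt_end, cal.STANDARD)
    new_dates = cal.date_range(tgt_start, n, cal.STANDARD)
    index = {(y, m, d): i for i, (y, m, d) in enumerate(map(tuple, new_dates))}
    new_vals = np.full((n,) + data.values.shape[1:], np.nan)
    filled = set()
    for src_i, (y, m, d) in enumerate(map(tuple, data.dates)):
        L = cal.month_lengths(y, cal.STANDARD)[m - 1]
        tgt = (y, m, (d - 1) * L // 30 + 1)
        if tgt in index and tgt not in filled:
            new_vals[index[tgt]] = data.values[src_i]
            filled.add(tgt)
    # trim leading pad before the first mapped date; keep the final month
    # complete so unmapped real dates (e.g. Dec 31) stay as missing slots
    keep = np.where([t in filled for t in map(tuple, new_dates)])[0]
    lo = keep[0]
    return replace(data, dates=new_dates[lo:], values=new_vals[lo:], calendar=cal.STANDARD)


def screen_outliers(data: GriddedTemperature, threshold: float = 60.0) -> GriddedTemperature:
    """Mask values strictly above `threshold` °C as missing."""
    with np.errstate(invalid="ignore"):
        mask = data.values > threshold
    n_removed = int(mask.sum())
    if n_removed:
        log.info("screen_outliers: removed %d values > %.1f degC", n_removed, threshold)
    vals = data.values.copy()
    vals[mask] = np.nan
    return replace(data, values=vals)


def standardize(data: GriddedTemperature, outlier_threshold: float = 60.0) -> GriddedTemperature:
    """Full standardization: 1° grid, standard calendar, outlier screen."""
    return screen_outliers(standardize_calendar(regrid_to_one_degree(data)), outlier_threshold)
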