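"""Per-cell series conditioning: gap filling, detrending, windowing.

Spectral estimation needs complete, trend-free daily series.  Gaps
(e.g. calendar-inserted Feb 29) are filled by linear interpolation in
time; the secular warming signal is removed by an ordinary least-squares
line fitted over the entire series; optionally the mean annual cycle is
removed as well.  Series are then partitioned into consecutive
non-overlapping multi-year windows (5-10 years) for windowed analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calendars as cal

WINDOW_SIZES = range(5, 11)


@dataclass(frozen=True)
class TimeWindow:
    """A contiguous block of calendar years, inclusive on both ends."""

    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.length not in WINDOW_SIZES:
            raise ValueError(f"window length {self.length} outside {{5..10}}")

    @property
    def length(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def midpoint(self) -> float:
        return (self.start_year + self.end_year) / 2.0

    def mask(self, years: np.ndarray) -> np.ndarray:
        return (years >= self.start_year) & (years <= self.end_year)


def partition_windows(start_year: int, end_year: int, window_years: int) -> list[TimeWindow]:
    """Consecutive non-overlapping windows; a trailing partial window is dropped."""
    if window_years not in WINDOW_SIZES:
        raise ValueError(f"window_years must be in {{5..10}}, got {window_years}")
    if end_year < start_year:
        raise ValueError("end_year precedes start_year")
    span = end_year - start_year + 1
    return [
        TimeWindow(start_year + i * window_years, start_year + (i + 1) * window_years - 1)
        for i in range(span // window_years)
    ]


def interpolate_gaps(series: np.ndarray) -> np.ndarray:
    """Fill missing values by linear interpolation in index space.

    Interior gaps are interpolated between the nearest valid neighbors;
    leading/trailing gaps take the nearest valid value, so the output
    length always equals the input length.
    """
    series = np.asarray(series, dtype=float)
    valid = np.isfinite(series)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid values to interpolate")
    if valid.all():
        return series.copy()
    idx = np.arange(len(series))
    return np.interp(idx, idx[valid], series[valid])


def linear_detrend(series: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Residuals of the OLS line of `series` on `times` (fit over the whole series)."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(series) < 3:
        raise ValueError("need at least 3 points to detrend")
    if np.ptp(times) == 0:
        raise ValueError("constant time vector")
    valid = np.isfinite(series)
    t0 = times.mean()
    slope, intercept = np.polyfit(times[valid] - t0, series[valid], 1)
    return series - (intercept + slope * (times - t0))


def seasonal_detrend(series: np.ndarray, dates: np.ndarray, calendar: str = cal.STANDARD) -> np.ndarray:
    """Subtract the mean annual temperature profile.

    The profile is the multi-year mean for each calendar (month, day);
    Feb 29 therefore averages over leap years only.  NaNs are ignored in
    the profile and preserved in the output.
    """
    series = np.asarray(series, dtype=float)
    dates = np.asarray(dates)
    if len(np.unique(dates[:, 0])) < 2:
        raise ValueError("need at least 2 years for a seasonal profile")
    key = dates[:, 1] * 100 + dates[:, 2]
    order = np.argsort(key, kind="stable")
    sk = key[order]
    boundaries = np.flatnonzero(np.diff(sk)) + 1
    out = np.empty_like(series)
    for grp in np.split(order, boundaries):
        vals = series[grp]
        finite = np.isfinite(vals)
        mean = vals[finite].mean() if finite.any() else np.nan
        out[grp] = vals - mean
    return out


def condition_series(
    series: np.ndarray,
    dates: np.ndarray,
    detrend: str = "linear",
    calendar: str = cal.STANDARD,
) -> np.ndarray:
    """Gap-fill then detrend a daily series.

    detrend="linear" removes only the secular OLS line (the annual cycle
    is retained; conservative for spectral trend detection).
    detrend="seasonal" removes the line and the mean annual profile
    (anti-conservative).
    """
    filled = interpolate_gaps(series)
    times = cal.decimal_year(dates, calendar)
    resid = linear_detrend(filled, times)
    if detrend == "seasonal":
        resid = seasonal_detrend(resid, dates, calendar)
    elif detrend != "linear":
        raise ValueError(f"detrend must be 'linear' or 'seasonal', got {detrend!r}")
    return resid
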