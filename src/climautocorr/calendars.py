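"""Minimal model-calendar arithmetic (standard, noleap, 360_day).

Climate models run on idealized calendars; daily output therefore cannot
always be represented with ordinary datetime types.  Dates are handled
here as (year, month, day) integer triples plus a calendar tag, which is
sufficient for decoding CF "days since ..." axes and for mapping model
calendars onto the real (leap-year aware) one.
"""

from __future__ import annotations

import numpy as np

from .exceptions import FormatError

STANDARD = "standard"
NOLEAP = "noleap"
CAL_360 = "360_day"

_ALIASES = {
    "standard": STANDARD,
    "gregorian": STANDARD,
    "proleptic_gregorian": STANDARD,
    "noleap": NOLEAP,
    "365_day": NOLEAP,
    "360_day": CAL_360,
}

_DAYS_STD = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)


def canonical_calendar(tag: str) -> str:
    try:
        return _ALIASES[str(tag).lower()]
    except KeyError:
        raise FormatError(f"unknown calendar tag {tag!r}") from None


def is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def month_lengths(year: int, calendar: str = STANDARD) -> tuple[int, ...]:
    calendar = canonical_calendar(calendar)
    if calendar == CAL_360:
        return (30,) * 12
    lengths = list(_DAYS_STD)
    if calendar == STANDARD and is_leap(year):
        lengths[1] = 29
    return tuple(lengths)


def year_length(year: int, calendar: str = STANDARD) -> int:
    return sum(month_lengths(year, calendar))


def date_range(start: tuple[int, int, int], n_days: int, calendar: str = STANDARD) -> np.ndarray:
    """Consecutive daily dates as an (n_days, 3) int array of (year, month, day)."""
    calendar = canonical_calendar(calendar)
    y, m, d = map(int, start)
    out = np.empty((n_days, 3), dtype=np.int64)
    lengths = month_lengths(y, calendar)
    for i in range(n_days):
        out[i] = (y, m, d)
        d += 1
        if d > lengths[m - 1]:
            d = 1
            m += 1
            if m > 12:
                m = 1
                y += 1
                lengths = month_lengths(y, calendar)
    return out


def date_span_days(start: tuple[int, int, int], end: tuple[int, int, int], calendar: str = STANDARD) -> int:
    """Number of days from start to end inclusive (end must not precede start)."""
    calendar = canonical_calendar(calendar)
    sy, sm, sd = map(int, start)
    ey, em, ed = map(int, end)

    def ordinal(y: int, m: int, d: int) -> int:
        # days since (sy, 1, 1)
        total = 0
        for yy in range(sy, y):
            total += year_length(yy, calendar)
        total += sum(month_lengths(y, calendar)[: m - 1]) + (d - 1)
        return total

    if (ey, em, ed) < (sy, sm, sd):
        raise ValueError("end precedes start")
    return ordinal(ey, em, ed) - ordinal(sy, sm, sd) + 1


def day_of_year(dates: np.ndarray, calendar: str = STANDARD) -> np.ndarray:
    """1-based day-of-year for an (n, 3) date array."""
    calendar = canonical_calendar(calendar)
    dates = np.asarray(dates)
    out = np.empty(len(dates), dtype=np.int64)
    cache: dict[int, np.ndarray] = {}
    for i, (y, m, d) in enumerate(dates):
        y = int(y)
        if y not in cache:
            cache[y] = np.concatenate([[0], np.cumsum(month_lengths(y, calendar))])
        out[i] = cache[y][m - 1] + d
    return out


def decimal_year(dates: np.ndarray, calendar: str = STANDARD) -> np.ndarray:
    """Continuous time axis in years, e.g. 2000-01-01 -> 2000.0."""
    calendar = canonical_calendar(calendar)
    doy = day_of_year(dates, calendar)
    years = np.asarray(dates)[:, 0].astype(float)
    lengths = np.array([year_length(int(y), calendar) for y in np.asarray(dates)[:, 0]], dtype=float)
    return years + (doy - 1) / lengths
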