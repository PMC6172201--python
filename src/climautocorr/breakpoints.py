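"""Piecewise-linear breakpoint ("tipping point") detection in metric trends.

A windowed metric series is segmented into 1..6 pieces (0..5 breaks),
each fitted by its own independent straight line; segment boundaries are
restricted to window boundaries and every segment must contain at least
``min_segment`` windows.  For each candidate break count the globally
RSS-optimal segmentation is found by exact dynamic programming, and the
break count is selected by the small-sample-corrected Akaike criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1) / (n - k - 1),

with k = 2(s+1) + s + 1 parameters for s breaks (two line coefficients
per segment, the break positions, and the residual variance).  Segments
are deliberately fitted as disconnected lines rather than a continuous
spline: the object of interest is the change in the local trend, and
per-segment intercepts/slopes are reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import EstimationError
from .trends import MIN_GLS_WINDOWS, TrendFit, TrendGLS

MAX_BREAKS = 5
DEFAULT_MIN_SEGMENT = 3
_RSS_FLOOR = 1e-300


@dataclass(frozen=True)
class BreakpointModel:
    """An optimal piecewise-linear segmentation of a metric series.

    break_years are the times of the first window of each post-break
    segment; segments hold (intercept, slope, p_value) of the
    independent per-segment OLS lines, in chronological order.
    """

    n_breaks: int
    break_years: tuple[float, ...]
    segments: tuple[tuple[float, float, float], ...]
    rss: float
    aicc: float
    n_points: int

    def __post_init__(self) -> None:
        if len(self.segments) != self.n_breaks + 1:
            raise ValueError("need exactly n_breaks + 1 segments")
        if np.any(np.diff(self.break_years) <= 0):
            raise ValueError("break years must be strictly increasing")

    def summary(self) -> str:
        lines = [
            f"Piecewise linear fit: {self.n_breaks} break(s), "
            f"n={self.n_points}, RSS={self.rss:.6g}, AICc={self.aicc:.6g}"
        ]
        labels = _segment_labels(self.n_breaks)
        for label, (b0, b1, p), in zip(labels, self.segments):
            star = " *" if p < 0.05 else ""
            lines.append(f"  {label:<16} intercept {b0:+.6g}  slope {b1:+.6g}  p={p:.3g}{star}")
        if self.break_years:
            lines.append("  break years: " + ", ".join(f"{y:g}" for y in self.break_years))
        return "\n".join(lines)


def _segment_labels(n_breaks: int) -> list[str]:
    if n_breaks == 0:
        return ["entire series"]
    return ["before break 1"] + [f"after break {i}" for i in range(1, n_breaks + 1)]


def _ols_line(values: np.ndarray, times: np.ndarray) -> tuple[float, float, float, float]:
    """(intercept, slope, p_value, rss) of an OLS line; degenerate-safe."""
    n = len(values)
    t0 = times.mean()
    if np.ptp(times) == 0:
        mean = values.mean()
        return float(mean), 0.0, 1.0, float(np.sum((values - mean) ** 2))
    slope, b0c = np.polyfit(times - t0, values, 1)
    resid = values - (b0c + slope * (times - t0))
    rss = float(resid @ resid)
    df = n - 2
    if df > 0:
        sxx = float(np.sum((times - t0) ** 2))
        s2 = rss / df if rss > 0 else 0.0
        se = np.sqrt(s2 / sxx)
        p = float(2 * stats.t.sf(abs(slope) / se, df)) if se > 0 else (1.0 if slope == 0 else 0.0)
    else:
        p = 1.0
    return float(b0c - slope * t0), float(slope), p, rss


def _segment_costs(values: np.ndarray, times: np.ndarray, min_segment: int) -> np.ndarray:
    """cost[i, j] = RSS of a line on points i..j-1 (inf when j - i < min_segment)."""
    n = len(values)
    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + min_segment, n + 1):
            t, v = times[i:j], values[i:j]
            cost[i, j] = _ols_line(v, t)[3]
    return cost


class PiecewiseTrendModel:
    """Exact RSS-optimal piecewise-linear segmentation with AICc selection.

    ``fit(n_breaks=s)`` returns the optimal s-break :class:`BreakpointModel`;
    ``fit()`` scans 0..max_breaks and returns the AICc minimizer (ties go
    to fewer breaks).  Break positions lie on window boundaries only.
    """

    def __init__(
        self,
        values: np.ndarray,
        times: np.ndarray,
        max_breaks: int = MAX_BREAKS,
        min_segment: int = DEFAULT_MIN_SEGMENT,
    ):
        values = np.asarray(values, dtype=float)
        times = np.asarray(times, dtype=float)
        if values.shape != times.shape or values.ndim != 1:
            raise ValueError("values and times must be 1-D arrays of equal length")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(times)):
            raise ValueError("values and times must be finite")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 0 <= max_breaks <= MAX_BREAKS:
            raise ValueError(f"max_breaks must be in 0..{MAX_BREAKS}")
        if min_segment < 2:
            raise ValueError("min_segment must be >= 2")
        self.values, self.times = values, times
        self.max_breaks, self.min_segment = max_breaks, min_segment
        self._cost = _segment_costs(values, times, min_segment)
        # fits at numerical zero RSS are ties, not improvements
        self._rss_floor = max(1e-12 * float(np.sum((values - values.mean()) ** 2)), _RSS_FLOOR)

    # -- exact search --------------------------------------------------
    def _dp(self, n_segments: int) -> tuple[float, list[int]]:
        """Optimal boundaries for a fixed segment count (ties -> earliest breaks)."""
        n = len(self.values)
        cost = self._cost
        # best[s][j]: optimal cost of covering points 0..j-1 with s segments
        best = np.full((n_segments + 1, n + 1), np.inf)
        back = np.zeros((n_segments + 1, n + 1), dtype=int)
        best[0, 0] = 0.0
        for s in range(1, n_segments + 1):
            for j in range(s * self.min_segment, n + 1):
                cands = best[s - 1, : j - self.min_segment + 1] + cost[: j - self.min_segment + 1, j]
                i = int(np.argmin(cands))  # argmin takes the first (earliest) on ties
                best[s, j], back[s, j] = cands[i], i
        if not np.isfinite(best[n_segments, n]):
            raise ValueError(
                f"{n_segments - 1} breaks infeasible for {n} points with "
                f"min_segment={self.min_segment}"
            )
        bounds = [n]
        j = n
        for s in range(n_segments, 0, -1):
            j = back[s, j]
            bounds.append(j)
        return float(best[n_segments, n]), bounds[::-1]

    def fit(self, n_breaks: int | None = None) -> BreakpointModel:
        if n_breaks is not None:
            return self._fit_fixed(n_breaks)
        best = None
        for s in range(self.max_breaks + 1):
            k = _n_params(s)
            if len(self.values) - k - 1 <= 0:
                continue
            try:
                model = self._fit_fixed(s)
            except ValueError:
                continue
            if best is None or model.aicc < best.aicc:
                best = model
        if best is None:
            raise EstimationError(
                f"no feasible break count for n={len(self.values)} points "
                f"(min_segment={self.min_segment})"
            )
        return best

    def _fit_fixed(self, n_breaks: int) -> BreakpointModel:
        if not 0 <= n_breaks <= self.max_breaks:
            raise ValueError(f"n_breaks must be in 0..{self.max_breaks}")
        rss, bounds = self._dp(n_breaks + 1)
        segments = []
        for i, j in zip(bounds[:-1], bounds[1:]):
            b0, b1, p, _ = _ols_line(self.values[i:j], self.times[i:j])
            segments.append((b0, b1, p))
        break_years = tuple(float(self.times[b]) for b in bounds[1:-1])
        return BreakpointModel(
            n_breaks=n_breaks,
            break_years=break_years,
            segments=tuple(segments),
            rss=rss,
            aicc=_aicc(max(rss, self._rss_floor), len(self.values), n_breaks),
            n_points=len(self.values),
        )


def _n_params(n_breaks: int) -> int:
    return 2 * (n_breaks + 1) + n_breaks + 1


def _aicc(rss: float, n: int, n_breaks: int) -> float:
    k = _n_params(n_breaks)
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# -- functional conveniences matching the analysis workflow ------------

def segmented_fit(
    values: np.ndarray,
    times: np.ndarray,
    n_breaks: int,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> BreakpointModel:
    """RSS-optimal segmentation with a fixed number of breaks."""
    return PiecewiseTrendModel(values, times, n_breaks, min_segment).fit(n_breaks)


def select_n_breaks(
    values: np.ndarray,
    times: np.ndarray,
    max_breaks: int = MAX_BREAKS,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> BreakpointModel:
    """AICc-selected break count in 0..max_breaks."""
    return PiecewiseTrendModel(values, times, max_breaks, min_segment).fit()


def segment_trends(
    values: np.ndarray,
    times: np.ndarray,
    break_years,
) -> list[tuple[str, TrendFit]]:
    """Chronologically labelled trend fits between given break years.

    Segments with >= 5 points use GLS with AR(1) errors; shorter
    segments (>= 3 points) fall back to OLS and are flagged by
    ``TrendFit.method == "ols"``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    break_years = sorted(float(b) for b in break_years)
    edges = [-np.inf] + break_years + [np.inf]
    out = []
    for label, (lo, hi) in zip(_segment_labels(len(break_years)), zip(edges[:-1], edges[1:])):
        mask = (times >= lo) & (times < hi)
        if mask.sum() < 3:
            raise EstimationError(f"segment {label!r} has {int(mask.sum())} < 3 points")
        v, t = values[mask], times[mask]
        if mask.sum() >= MIN_GLS_WINDOWS:
            fit = TrendGLS(v, t).fit()
        else:
            fit = _ols_trendfit(v, t)
        out.append((label, fit))
    return out


def _ols_trendfit(values: np.ndarray, times: np.ndarray) -> TrendFit:
    b0, b1, p, rss = _ols_line(values, times)
    n = len(values)
    df = max(n - 2, 1)
    sxx = float(np.sum((times - times.mean()) ** 2))
    se = np.sqrt((rss / df) / sxx) if sxx > 0 else np.inf
    tcrit = stats.t.ppf(0.975, df)
    return TrendFit(
        slope=b1, intercept=b0, slope_se=float(se), p_value=p,
        ci95=(b1 - tcrit * se, b1 + tcrit * se), ar1_phi=0.0,
        n_windows=n, method="ols",
    )
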