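"""Autocorrelation metrics: spectral exponent and variogram spatial range.

Temporal autocorrelation of a daily series is summarized by the spectral
exponent: the OLS slope of log power against log frequency of the
periodogram.  More negative exponents mean variance concentrated at low
frequencies ("redder" noise, more temporal memory).

Spatial autocorrelation of a temperature field is summarized by the
spatial range: the distance (km) at which the semivariance of the field
plateaus.  It is estimated by fitting a Gaussian variogram model
``gamma(h) = c0 + c * (1 - exp(-(h/a)^2))`` to the empirical variogram by
weighted least squares; the reported range is the practical range
``sqrt(3) * a``, where the model reaches 95% of its sill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .exceptions import EstimationError

EARTH_RADIUS_KM = 6371.0
MIN_SPECTRAL_BINS = 8
MIN_VARIOGRAM_CELLS = 30
MIN_VARIOGRAM_BINS = 6

REGIONS = ("global", "tropics", "temperate")
TROPICS_LAT = 23.5
TEMPERATE_LAT = 66.0


# ---------------------------------------------------------------------
# temporal: periodogram and spectral exponent
# ---------------------------------------------------------------------

def periodogram(series: np.ndarray, sample_spacing_days: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (zero frequency excluded).

    Returns (frequencies in cycles/day, power spectral density in
    °C²·day).  Normalization is such that sum(power) * Δf equals the
    series variance (Parseval).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 16:
        raise ValueError(f"series too short for a periodogram ({len(series)} < 16)")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains missing values; interpolate first")
    freqs, power = signal.periodogram(
        series, fs=1.0 / sample_spacing_days, detrend="constant", scaling="density"
    )
    return freqs[1:], power[1:]


@dataclass(frozen=True)
class SpectralFit:
    """Log-log periodogram regression for one cell/window.

    ``exponent`` is the OLS slope of log power on log frequency (base
    invariant); more negative = greater temporal autocorrelation.
    """

    exponent: float
    intercept: float
    r_squared: float
    n_freqs: int
    freq_band: tuple[float, float]

    def summary(self) -> str:
        lo, hi = self.freq_band
        return (
            "Spectral exponent fit\n"
            f"  exponent   {self.exponent:+.4f}\n"
            f"  intercept  {self.intercept:+.4f} (ln power at ln f = 0)\n"
            f"  R^2        {self.r_squared:.4f}\n"
            f"  bins       {self.n_freqs} in [{lo:.3g}, {hi:.3g}] cycles/day"
        )


def spectral_exponent(frequencies: np.ndarray, power: np.ndarray) -> SpectralFit:
    """OLS fit of log power against log frequency (zero-power bins dropped)."""
    frequencies = np.asarray(frequencies, dtype=float)
    power = np.asarray(power, dtype=float)
    usable = (frequencies > 0) & (power > 0) & np.isfinite(power)
    if usable.sum() < MIN_SPECTRAL_BINS:
        raise EstimationError(
            f"only {int(usable.sum())} usable frequency bins (< {MIN_SPECTRAL_BINS})"
        )
    lf = np.log(frequencies[usable])
    lp = np.log(power[usable])
    slope, intercept = np.polyfit(lf, lp, 1)
    resid = lp - (intercept + slope * lf)
    ss_tot = np.sum((lp - lp.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return SpectralFit(
        exponent=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        n_freqs=int(usable.sum()),
        freq_band=(float(frequencies[usable].min()), float(frequencies[usable].max())),
    )


class SpectralExponentModel:
    """Spectral-exponent estimator for one gap-free, detrended daily series.

    Thin model wrapper: ``SpectralExponentModel(series).fit()`` returns a
    :class:`SpectralFit`.
    """

    def __init__(self, series: np.ndarray, sample_spacing_days: float = 1.0):
        self.series = np.asarray(series, dtype=float)
        self.sample_spacing_days = sample_spacing_days

    def fit(self) -> SpectralFit:
        freqs, power = periodogram(self.series, self.sample_spacing_days)
        return spectral_exponent(freqs, power)


# ---------------------------------------------------------------------
# spatial: distances, empirical variogram, Gaussian model fit
# ---------------------------------------------------------------------

def great_circle_km(p1, p2) -> float:
    """Haversine great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (*np.asarray(p1, float), *np.asarray(p2, float)))
    return float(_haversine(lat1, lon1, lat2, lon2))


def _haversine(lat1, lon1, lat2, lon2):
    s = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(s, 0.0, 1.0)))


@dataclass(frozen=True)
class EmpiricalVariogram:
    """Binned semivariance against great-circle lag (empty bins removed)."""

    lag_centers: np.ndarray
    semivariance: np.ndarray
    pair_counts: np.ndarray
    max_lag: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_centers) <= 0):
            raise ValueError("lag centers must be strictly increasing")
        if np.any(self.semivariance < 0) or np.any(self.pair_counts <= 0):
            raise ValueError("semivariance must be >= 0 and pair counts > 0")


def _pairs_from_flat(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map flat upper-triangle pair indices k in [0, n(n-1)/2) to (i, j), i < j."""
    # rows i contribute (n-1-i) pairs; invert the cumulative count analytically
    i = (n - 2 - np.floor(np.sqrt(-8.0 * k + 4.0 * n * (n - 1) - 7) / 2.0 - 0.5)).astype(np.int64)
    j = (k + i + 1 - (i * (2 * n - i - 1)) // 2).astype(np.int64)
    return i, j


def empirical_variogram(
    field: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    n_bins: int = 30,
    max_lag: float | None = None,
    pair_budget: int = 1_000_000,
    seed: int | None = None,
) -> EmpiricalVariogram:
    """Empirical semivariogram of a (possibly masked) cell field.

    ``gamma(h-bin)`` is the mean over pairs in the bin of half the squared
    value difference.  When the full pair set exceeds ``pair_budget``,
    pairs are subsampled without replacement using ``seed``.  ``max_lag``
    defaults to half the maximum observed pairwise distance.
    """
    field = np.asarray(field, dtype=float).ravel()
    lats = np.asarray(lats, dtype=float).ravel()
    lons = np.asarray(lons, dtype=float).ravel()
    valid = np.isfinite(field)
    field, lats, lons = field[valid], lats[valid], lons[valid]
    n = len(field)
    if n < MIN_VARIOGRAM_CELLS:
        raise EstimationError(f"only {n} non-missing cells (< {MIN_VARIOGRAM_CELLS})")

    n_pairs = n * (n - 1) // 2
    if n_pairs <= pair_budget:
        k = np.arange(n_pairs, dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        draw = rng.integers(0, n_pairs, size=int(pair_budget * 1.25))
        k = np.unique(draw)[:pair_budget]
    i, j = _pairs_from_flat(k, n)

    rlat, rlon = np.radians(lats), np.radians(lons)
    dist = _haversine(rlat[i], rlon[i], rlat[j], rlon[j])
    sq = 0.5 * (field[i] - field[j]) ** 2

    if max_lag is None:
        max_lag = float(dist.max()) / 2.0
    inside = dist <= max_lag
    dist, sq = dist[inside], sq[inside]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq, minlength=n_bins)
    keep = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return EmpiricalVariogram(
        lag_centers=centers[keep],
        semivariance=sums[keep] / counts[keep],
        pair_counts=counts[keep],
        max_lag=float(max_lag),
    )


@dataclass(frozen=True)
class VariogramFit:
    """Gaussian variogram model fitted to an empirical variogram.

    gamma_hat(h) = nugget + partial_sill * (1 - exp(-(h / shape)^2));
    the spatial range reported downstream is ``practical_range`` =
    sqrt(3) * shape, where the model reaches 95% of its sill.
    """

    nugget: float
    partial_sill: float
    shape: float
    sse: float
    model: str = "gaussian"

    @property
    def practical_range(self) -> float:
        return float(np.sqrt(3.0) * self.shape)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def is_degenerate(self) -> bool:
        """True when there is no resolvable spatial structure (flat variogram)."""
        total = self.nugget + self.partial_sill
        return total <= 0 or self.partial_sill < 1e-6 * max(total, 1e-300)

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.nugget + self.partial_sill * (1.0 - np.exp(-((h / self.shape) ** 2)))

    def summary(self) -> str:
        lines = [
            "Gaussian variogram fit",
            f"  nugget (c0)       {self.nugget:.6g} degC^2",
            f"  partial sill (c)  {self.partial_sill:.6g} degC^2",
            f"  shape (a)         {self.shape:.6g} km",
            f"  practical range   {self.practical_range:.6g} km (sqrt(3)*a)",
            f"  weighted SSE      {self.sse:.6g}",
        ]
        if self.is_degenerate:
            lines.append("  [degenerate: no spatial structure, range undefined]")
        return "\n".join(lines)


def _gaussian_gamma(h, c0, c, a):
    return c0 + c * (1.0 - np.exp(-((h / a) ** 2)))


class GaussianVariogramModel:
    """Weighted least-squares Gaussian-model fit to an empirical variogram.

    Weights are the per-bin pair counts.  The optimization is multi-start
    (data-driven initial values over a spread of candidate ranges) to
    avoid local minima; bounds keep nugget and partial sill nonnegative
    and the shape parameter positive.
    """

    N_STARTS = 5

    def __init__(self, variogram: EmpiricalVariogram):
        if len(variogram.lag_centers) < MIN_VARIOGRAM_BINS:
            raise EstimationError(
                f"need >= {MIN_VARIOGRAM_BINS} variogram bins, got {len(variogram.lag_centers)}"
            )
        self.variogram = variogram

    def fit(self) -> VariogramFit:
        vg = self.variogram
        h, g, w = vg.lag_centers, vg.semivariance, np.sqrt(vg.pair_counts.astype(float))
        gmax = float(g.max())
        scale = gmax if gmax > 0 else 1.0
        c0_init = float(max(g[0], 0.0))
        c_init = max(gmax - c0_init, 0.1 * scale)
        hmax = float(h.max())
        best = None
        for frac in np.linspace(0.15, 1.0, self.N_STARTS):
            x0 = np.array([c0_init, c_init, max(frac * hmax / np.sqrt(3.0), 1e-6 * hmax)])
            try:
                # shape capped at 2x the largest lag: beyond that the data
                # carry no curvature information and the range is extrapolation
                res = optimize.least_squares(
                    lambda p: w * (_gaussian_gamma(h, *p) - g),
                    x0,
                    bounds=([0.0, 0.0, 1e-9 * hmax], [np.inf, np.inf, 2.0 * hmax]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            sse = float(np.sum(res.fun**2))
            if best is None or sse < best[0]:
                best = (sse, res.x)
        if best is None:
            raise EstimationError("Gaussian variogram fit failed to converge from all starts")
        sse, (c0, c, a) = best
        return VariogramFit(nugget=float(c0), partial_sill=float(c), shape=float(a), sse=sse)


def fit_gaussian_variogram(vg: EmpiricalVariogram) -> VariogramFit:
    """Functional convenience for :class:`GaussianVariogramModel`."""
    return GaussianVariogramModel(vg).fit()


# ---------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------

def regional_cells(lats: np.ndarray, region: str) -> np.ndarray:
    """Boolean mask of cells in a latitude band.

    tropics: |lat| <= 23.5; temperate: 23.5 < |lat| <= 66; global: all.
    Poleward of 66° is excluded from both regional analyses.
    """
    lats = np.abs(np.asarray(lats, dtype=float))
    if region == "global":
        return np.ones(lats.shape, dtype=bool)
    if region == "tropics":
        return lats <= TROPICS_LAT
    if region == "temperate":
        return (lats > TROPICS_LAT) & (lats <= TEMPERATE_LAT)
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


# ---------------------------------------------------------------------
# windowed metrics on a gridded dataset
# ---------------------------------------------------------------------

def _conditioned_matrix(data, detrend: str) -> np.ndarray:
    """(n_time, n_cells) matrix of gap-filled, detrended cell series.

    Cells with fewer than two valid values are unusable and come back
    all-NaN.  The linear detrend is fitted over the entire series; the
    optional seasonal detrend removes the mean (month, day) profile.
    """
    nt = data.n_time
    Y = data.values.reshape(nt, -1).astype(float).copy()
    idx = np.arange(nt)
    finite = np.isfinite(Y)
    usable = finite.sum(axis=0) >= 2
    for c in np.flatnonzero(usable & ~finite.all(axis=0)):
        v = finite[:, c]
        Y[:, c] = np.interp(idx, idx[v], Y[v, c])
    Y[:, ~usable] = np.nan
    times = data.decimal_year()
    X = np.column_stack([np.ones(nt), times - times.mean()])
    beta = np.zeros((2, Y.shape[1]))
    beta[:, usable], *_ = np.linalg.lstsq(X, Y[:, usable], rcond=None)
    Y -= X @ beta
    if detrend == "seasonal":
        key = data.dates[:, 1] * 100 + data.dates[:, 2]
        order = np.argsort(key, kind="stable")
        boundaries = np.flatnonzero(np.diff(key[order])) + 1
        for grp in np.split(order, boundaries):
            Y[grp] -= Y[grp].mean(axis=0)
    elif detrend != "linear":
        raise ValueError(f"detrend must be 'linear' or 'seasonal', got {detrend!r}")
    return Y


def windowed_spectral_exponents(
    data, windows, detrend: str = "linear", conditioned: np.ndarray | None = None
) -> np.ndarray:
    """Per-cell spectral exponent in each time window.

    `data` is a standardized GriddedTemperature; `windows` a list of
    TimeWindow.  Returns an array of shape (n_windows, n_lat, n_lon);
    unusable cells are NaN.  Conditioning (gap interpolation, linear
    detrend over the entire series, optional seasonal detrend) happens
    once; the exponent is then estimated on each window's segment.  A
    precomputed conditioned matrix (from :func:`_conditioned_matrix`)
    may be passed to avoid recomputation across window sizes.
    """
    Y = _conditioned_matrix(data, detrend) if conditioned is None else conditioned
    years = data.years
    nlat, nlon = len(data.lat), len(data.lon)
    out = np.full((len(windows), nlat, nlon), np.nan)
    for w_i, win in enumerate(windows):
        seg = Y[win.mask(years)]
        if len(seg) < 16:
            continue
        freqs, power = signal.periodogram(seg, fs=1.0, detrend="constant",
                                          scaling="density", axis=0)
        freqs, power = freqs[1:], power[1:]
        lf = np.log(freqs)
        lf_c = lf - lf.mean()
        denom = float(lf_c @ lf_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.log(power)
        good = np.all(np.isfinite(lp), axis=0) & np.isfinite(seg).all(axis=0)
        slopes = np.full(Y.shape[1], np.nan)
        slopes[good] = lf_c @ (lp[:, good] - lp[:, good].mean(axis=0)) / denom
        # cells with zero-power bins: drop those bins cell by cell
        for c in np.flatnonzero(~good & np.isfinite(seg).all(axis=0)):
            try:
                slopes[c] = spectral_exponent(freqs, power[:, c]).exponent
            except EstimationError:
                pass
        out[w_i] = slopes.reshape(nlat, nlon)
    return out


def windowed_spatial_ranges(
    data,
    windows,
    region: str = "global",
    aggregate: str = "yearly",
    n_bins: int = 30,
    max_lag: float | None = None,
    pair_budget: int = 1_000_000,
    seed: int | None = None,
) -> tuple[np.ndarray, list]:
    """Per-window variogram practical range (km) over a region's cells.

    With ``aggregate="yearly"`` (default) the empirical variogram of
    each year's mean field inside the window is computed on a shared
    set of (seeded) cell pairs and bins, and the per-year semivariances
    are pooled before the Gaussian-model fit.  Pooling averages
    independent field realizations in the variogram itself, which is
    substantially more stable than the variogram of the window-mean
    field (an average of k fields is still a single realization).
    ``aggregate="mean"``/``"median"`` use the window-aggregate field
    instead.

    Returns (ranges, fits); a window whose fit fails, is degenerate, or
    whose practical range exceeds twice the largest observed lag (pure
    extrapolation beyond the domain) gets NaN (the fit object, when one
    exists, is still returned for diagnostics).
    """
    if aggregate not in ("yearly", "mean", "median"):
        raise ValueError("aggregate must be 'yearly', 'mean' or 'median'")
    glat, glon = np.meshgrid(data.lat, data.lon, indexing="ij")
    mask = regional_cells(glat.ravel(), region)
    lats, lons = glat.ravel()[mask], glon.ravel()[mask]
    n = int(mask.sum())
    if n < MIN_VARIOGRAM_CELLS:
        raise EstimationError(f"only {n} cells in region {region!r}")
    years = data.years
    flat = data.values.reshape(data.n_time, -1)[:, mask]

    # shared pair sample, distances and bins across all windows
    n_pairs = n * (n - 1) // 2
    if n_pairs <= pair_budget:
        k = np.arange(n_pairs, dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        k = np.unique(rng.integers(0, n_pairs, size=int(pair_budget * 1.25)))[:pair_budget]
    pi, pj = _pairs_from_flat(k, n)
    rlat, rlon = np.radians(lats), np.radians(lons)
    dist = _haversine(rlat[pi], rlon[pi], rlat[pj], rlon[pj])
    lag_cap = float(dist.max()) / 2.0 if max_lag is None else float(max_lag)
    inside = dist <= lag_cap
    pi, pj, dist = pi[inside], pj[inside], dist[inside]
    edges = np.linspace(0.0, lag_cap, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def _binned(fields: np.ndarray) -> EmpiricalVariogram:
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for z in fields:
            sq = 0.5 * (z[pi] - z[pj]) ** 2
            ok = np.isfinite(sq)
            sums += np.bincount(which[ok], weights=sq[ok], minlength=n_bins)
            counts += np.bincount(which[ok], minlength=n_bins)
        keep = counts > 0
        if keep.sum() < MIN_VARIOGRAM_BINS:
            raise EstimationError("too few populated variogram bins")
        return EmpiricalVariogram(
            lag_centers=centers[keep],
            semivariance=sums[keep] / counts[keep],
            pair_counts=counts[keep],
            max_lag=lag_cap,
        )

    ranges = np.full(len(windows), np.nan)
    fits: list = []
    for w_i, win in enumerate(windows):
        seg = flat[win.mask(years)]
        seg_years = years[win.mask(years)]
        with np.errstate(invalid="ignore"):
            if aggregate == "yearly":
                fields = np.stack(
                    [np.nanmean(seg[seg_years == y], axis=0) for y in np.unique(seg_years)]
                )
            elif aggregate == "mean":
                fields = np.nanmean(seg, axis=0)[None, :]
            else:
                fields = np.nanmedian(seg, axis=0)[None, :]
        fit = None
        try:
            vg = _binned(fields)
            fit = GaussianVariogramModel(vg).fit()
            if not fit.is_degenerate and fit.practical_range <= 2.0 * vg.max_lag:
                ranges[w_i] = fit.practical_range
        except EstimationError:
            pass
        fits.append(fit)
    return ranges, fits
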