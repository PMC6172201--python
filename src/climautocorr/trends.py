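"""Trends in windowed autocorrelation metrics, and ensemble statistics.

The per-window metric series (spectral exponent or spatial range against
window midpoint year) are short (6-45 points) and serially correlated,
so trends are fitted by generalized least squares with an AR(1) residual
correlation.  The AR(1) coefficient is profiled out of the (restricted)
Gaussian likelihood using the Prais-Winsten transform; slope inference
uses a t reference distribution with n - 2 degrees of freedom.

Ensemble statistics follow the usual multimodel conventions:

* agreement  — fraction of members whose trend slope has the same sign
  as the multimodel-mean trend;
* robustness — fraction with the same sign AND an individually
  significant trend (p < alpha); robustness <= agreement by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gridio import GriddedTemperature

log = logging.getLogger(__name__)

MIN_GLS_WINDOWS = 5


@dataclass(frozen=True)
class TrendFit:
    """A fitted linear trend (metric units per year) with AR(1) errors."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    ci95: tuple[float, float]
    ar1_phi: float
    n_windows: int
    method: str = "gls-ar1"  # "ols" when AR(1) estimation was skipped or failed

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def predict(self, times: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(times, dtype=float)

    def summary(self) -> str:
        lo, hi = self.ci95
        return (
            f"Trend fit ({self.method}, n={self.n_windows})\n"
            f"  slope      {self.slope:+.6g} per year  (se {self.slope_se:.3g})\n"
            f"  intercept  {self.intercept:+.6g}\n"
            f"  95% CI     [{lo:+.6g}, {hi:+.6g}]\n"
            f"  p-value    {self.p_value:.4g}\n"
            f"  AR(1) phi  {self.ar1_phi:+.3f}"
        )


def _pw_transform(y: np.ndarray, X: np.ndarray, phi: float):
    """Prais-Winsten innovations of y and X under AR(1) correlation phi."""
    z = np.empty_like(y)
    Z = np.empty_like(X)
    r = np.sqrt(1.0 - phi * phi)
    z[0], Z[0] = r * y[0], r * X[0]
    z[1:] = y[1:] - phi * y[:-1]
    Z[1:] = X[1:] - phi * X[:-1]
    return z, Z


class TrendGLS:
    """GLS linear trend with AR(1) errors, phi estimated by (RE)ML.

    ``TrendGLS(values, times).fit()`` returns a :class:`TrendFit`.  With
    ``phi=0.0`` passed to :meth:`fit` the estimate reduces exactly to
    ordinary least squares.  Windows are assumed equally spaced in time
    (the AR(1) correlation acts on the window index).
    """

    def __init__(self, values: np.ndarray, times: np.ndarray):
        values = np.asarray(values, dtype=float)
        times = np.asarray(times, dtype=float)
        if values.shape != times.shape or values.ndim != 1:
            raise ValueError("values and times must be 1-D arrays of equal length")
        ok = np.isfinite(values) & np.isfinite(times)
        self.values, self.times = values[ok], times[ok]
        if len(self.values) < MIN_GLS_WINDOWS:
            raise ValueError(
                f"need >= {MIN_GLS_WINDOWS} windows for a trend fit, got {len(self.values)}"
            )
        self._t0 = self.times.mean()
        self.X = np.column_stack([np.ones_like(self.times), self.times - self._t0])

    def _neg_criterion(self, phi: float, reml: bool) -> float:
        y, X = self.values, self.X
        n, p = X.shape
        z, Z = _pw_transform(y, X, phi)
        beta, *_ = np.linalg.lstsq(Z, z, rcond=None)
        rss = float(np.sum((z - Z @ beta) ** 2))
        rss = max(rss, 1e-300)
        if reml:
            sign, logdet = np.linalg.slogdet(Z.T @ Z)
            return (n - p) * np.log(rss) - np.log1p(-phi * phi) + logdet
        return n * np.log(rss) - np.log1p(-phi * phi)

    def fit(self, phi: float | None = None, reml: bool = True, bias_correct: bool = True) -> TrendFit:
        """Fit the trend; phi=None profiles the AR(1) coefficient out of the
        (restricted) likelihood and, when ``bias_correct`` is set, applies the
        Kendall small-sample correction phi + (1 + 3 phi)/n before inference
        (the ML estimate of phi is biased low at the short series lengths
        used here, which would understate the slope standard error)."""
        y, X = self.values, self.X
        n, p = X.shape
        method = "gls-ar1"
        if phi is None:
            try:
                res = optimize.minimize_scalar(
                    self._neg_criterion,
                    bounds=(-0.99, 0.99),
                    args=(reml,),
                    method="bounded",
                    options={"xatol": 1e-6},
                )
                phi = float(res.x) if res.success and np.isfinite(res.x) else 0.0
                if not res.success:
                    method = "ols"
                    log.warning("AR(1) profile optimization failed; falling back to OLS")
            except Exception:
                phi, method = 0.0, "ols"
                log.warning("AR(1) profile optimization raised; falling back to OLS")
            if bias_correct and method == "gls-ar1":
                phi = float(np.clip(phi + (1.0 + 3.0 * phi) / n, -0.99, 0.99))
        elif phi == 0.0:
            method = "ols"
        z, Z = _pw_transform(y, X, phi)
        beta, *_ = np.linalg.lstsq(Z, z, rcond=None)
        resid = z - Z @ beta
        df = n - p
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(Z.T @ Z)
        slope, slope_se = float(beta[1]), float(np.sqrt(cov[1, 1]))
        intercept = float(beta[0] - beta[1] * self._t0)
        if slope_se > 0:
            tval = slope / slope_se
            p_value = float(2.0 * stats.t.sf(abs(tval), df))
        else:
            p_value = 0.0 if slope != 0 else 1.0
        tcrit = stats.t.ppf(0.975, df)
        return TrendFit(
            slope=slope,
            intercept=intercept,
            slope_se=slope_se,
            p_value=p_value,
            ci95=(slope - tcrit * slope_se, slope + tcrit * slope_se),
            ar1_phi=float(phi),
            n_windows=n,
            method=method,
        )


def gls_trend(values: np.ndarray, times: np.ndarray) -> TrendFit:
    """Functional convenience for ``TrendGLS(values, times).fit()``."""
    return TrendGLS(values, times).fit()


# ---------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------

def multimodel_mean(datasets: list[GriddedTemperature]) -> GriddedTemperature:
    """Cellwise mean temperature across ensemble members.

    A cell-time missing in some members averages the available ones.
    """
    if not datasets:
        raise ValueError("empty ensemble")
    ref = datasets[0]
    for d in datasets[1:]:
        if (
            not np.array_equal(d.lat, ref.lat)
            or not np.array_equal(d.lon, ref.lon)
            or not np.array_equal(d.dates, ref.dates)
            or d.calendar != ref.calendar
        ):
            raise ValueError("ensemble members must share grid and calendar")
    if len(datasets) == 1:
        return ref
    stack = np.stack([d.values for d in datasets])
    counts = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nansum(stack, axis=0) / np.where(counts > 0, counts, 1)
    mean[counts == 0] = np.nan
    return _dc_replace(ref, values=mean)


@dataclass(frozen=True)
class EnsembleSummary:
    """Sign agreement and significance robustness of an ensemble of trends."""

    reference_sign: int
    reference_fit: TrendFit
    per_model_fits: list[TrendFit]
    agreement: float
    robustness: float
    alpha: float = 0.05

    @property
    def n_models(self) -> int:
        return len(self.per_model_fits)

    def summary(self) -> str:
        return (
            f"Ensemble of {self.n_models} members (alpha={self.alpha})\n"
            f"  multimodel slope {self.reference_fit.slope:+.6g} per year "
            f"(p={self.reference_fit.p_value:.4g})\n"
            f"  agreement   {self.agreement:.3f}\n"
            f"  robustness  {self.robustness:.3f}"
        )


def _sign(x: float) -> int:
    return 1 if x > 0 else (-1 if x < 0 else 0)


def ensemble_summary(
    per_model_values: np.ndarray,
    multimodel_values: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
) -> EnsembleSummary:
    """Agreement/robustness of per-member trends against the multimodel trend.

    A member slope of exactly zero counts against agreement.  Both
    statistics are exact multiples of 1/M.
    """
    per_model_values = np.atleast_2d(np.asarray(per_model_values, dtype=float))
    ref_fit = gls_trend(multimodel_values, times)
    ref_sign = _sign(ref_fit.slope) or 1
    fits = [gls_trend(v, times) for v in per_model_values]
    same = [f for f in fits if _sign(f.slope) == ref_sign]
    m = len(per_model_values)
    agreement = len(same) / m
    robustness = sum(1 for f in same if f.p_value < alpha) / m
    return EnsembleSummary(
        reference_sign=ref_sign,
        reference_fit=ref_fit,
        per_model_fits=fits,
        agreement=agreement,
        robustness=robustness,
        alpha=alpha,
    )


# ---------------------------------------------------------------------
# per-cell maps and their latitudinal/longitudinal summaries
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class CellTrendMaps:
    """Per-cell trend of a windowed metric plus ensemble maps."""

    lat: np.ndarray
    lon: np.ndarray
    slope: np.ndarray
    p_value: np.ndarray
    agreement: np.ndarray
    robustness: np.ndarray

    def to_xarray(self):
        import xarray as xr

        return xr.Dataset(
            {
                name: (("lat", "lon"), getattr(self, name))
                for name in ("slope", "p_value", "agreement", "robustness")
            },
            coords={"lat": self.lat, "lon": self.lon},
        )


def cell_slope_map(
    per_model_metric: np.ndarray,
    multimodel_metric: np.ndarray,
    times: np.ndarray,
    lat: np.ndarray,
    lon: np.ndarray,
    alpha: float = 0.05,
) -> CellTrendMaps:
    """Per-cell GLS trend of a windowed metric with ensemble agreement maps.

    ``multimodel_metric`` has shape (n_windows, n_lat, n_lon) and
    ``per_model_metric`` (n_models, n_windows, n_lat, n_lon); cells whose
    series contain missing values are left missing in all maps.
    """
    per_model_metric = np.asarray(per_model_metric, dtype=float)
    nlat, nlon = len(lat), len(lon)
    slope = np.full((nlat, nlon), np.nan)
    pval = np.full((nlat, nlon), np.nan)
    agree = np.full((nlat, nlon), np.nan)
    robust = np.full((nlat, nlon), np.nan)
    for i in range(nlat):
        for j in range(nlon):
            series = multimodel_metric[:, i, j]
            if not np.all(np.isfinite(series)):
                continue
            try:
                summ = ensemble_summary(
                    per_model_metric[:, :, i, j], series, times, alpha=alpha
                )
            except ValueError:
                continue
            slope[i, j] = summ.reference_fit.slope
            pval[i, j] = summ.reference_fit.p_value
            agree[i, j] = summ.agreement
            robust[i, j] = summ.robustness
    return CellTrendMaps(
        lat=np.asarray(lat), lon=np.asarray(lon),
        slope=slope, p_value=pval, agreement=agree, robustness=robust,
    )


def latitudinal_summary(maps: CellTrendMaps, axis: str = "lat") -> pd.DataFrame:
    """Percent of valid cells per latitude (or longitude) in each category.

    Columns: pct_negative_slope (redder / more autocorrelated),
    pct_positive_slope, pct_agreement_gt50, pct_robustness_gt50.
    Rows with no valid cell hold NaN.
    """
    if axis not in ("lat", "lon"):
        raise ValueError("axis must be 'lat' or 'lon'")
    coords = maps.lat if axis == "lat" else maps.lon
    rows = []
    for k, coord in enumerate(coords):
        sl = maps.slope[k, :] if axis == "lat" else maps.slope[:, k]
        ag = maps.agreement[k, :] if axis == "lat" else maps.agreement[:, k]
        rb = maps.robustness[k, :] if axis == "lat" else maps.robustness[:, k]
        valid = np.isfinite(sl)
        n = int(valid.sum())
        if n == 0:
            rows.append({axis: coord, "n_cells": 0, "pct_negative_slope": np.nan,
                         "pct_positive_slope": np.nan, "pct_agreement_gt50": np.nan,
                         "pct_robustness_gt50": np.nan})
            continue
        rows.append(
            {
                axis: coord,
                "n_cells": n,
                "pct_negative_slope": 100.0 * np.sum(sl[valid] < 0) / n,
                "pct_positive_slope": 100.0 * np.sum(sl[valid] > 0) / n,
                "pct_agreement_gt50": 100.0 * np.sum(ag[valid] > 0.5) / n,
                "pct_robustness_gt50": 100.0 * np.sum(rb[valid] > 0.5) / n,
            }
        )
    return pd.DataFrame(rows)
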