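"""Synthetic daily temperature fields with known autocorrelation structure.

Every downstream estimator (spectral exponent, variogram range, GLS
trend, breakpoint selection) is validated by parameter recovery on
fields generated here with known ground truth:

* per-cell temporal noise is 1/f^beta colored noise synthesized in the
  frequency domain (amplitudes proportional to f^(-beta/2), uniform
  random phases, zero DC), so the imposed spectrum is exactly the one
  the estimator models;
* a time-varying spectral exponent (reddening) is realized by
  modulating each Fourier component's amplitude with the instantaneous
  target spectrum, f_k^(-beta(t)/2); a window centred at time t then
  has local spectrum proportional to f^(-beta(t)), so the per-window
  estimated exponent tracks -beta(t) linearly.  The modulation is
  evaluated through a truncated exponential-series expansion, which
  reduces it to a few dozen FFTs per batch of cells;
* spatial correlation is carried by Gaussian random fields with a
  Gaussian covariance (practical range = sqrt(3) * shape, great-circle
  distances), drawn by covariance-matrix factorization and redrawn
  independently each calendar year (piecewise-constant within a year);
* on top: a constant base temperature, a linear warming trend, an
  annual sinusoid keyed to (month, day), optional leap-day gaps
  (noleap calendar), and rare injected outliers above 60 degC.

Space and time are generated separably; this is an artifact of the
testbed, not a claim about real climate fields (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft

from . import calendars as cal
from .autocorr import EARTH_RADIUS_KM, _haversine
from .gridio import GriddedTemperature

SPATIAL_BLOCK_YEARS = 1  # spatial fields are redrawn every this many years


def generate_colored_noise(n: int, beta: float, seed) -> np.ndarray:
    """Unit-variance 1/f^beta noise of length n (frequency-domain synthesis)."""
    noise = _colored_noise_matrix(n, beta, np.random.default_rng(seed), n_series=1)
    return noise[0]


def _colored_noise_matrix(n: int, beta: float, rng: np.random.Generator, n_series: int) -> np.ndarray:
    """(n_series, n) array of independent unit-variance 1/f^beta series."""
    if n < 16:
        raise ValueError(f"need n >= 16, got {n}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    freqs = np.fft.rfftfreq(n)  # cycles per sample; freqs[0] = 0
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_series, len(freqs)))
    spectrum = amp * np.exp(1j * phases)
    spectrum[:, 0] = 0.0
    if n % 2 == 0:
        spectrum[:, -1] = spectrum[:, -1].real  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ramped_noise_matrix(
    n: int,
    beta_start: float,
    beta_end: float,
    rng: np.random.Generator,
    n_series: int,
    freq_floor: float | None = None,
    dtype=np.float64,
) -> np.ndarray:
    """(n_series, n) noise whose local spectrum ramps from f^-beta_start to f^-beta_end.

    Each Fourier component k carries a slowly drifting amplitude
    f_k^(-beta(t)/2) with beta(t) linear in t.  Writing
    f^(-beta(t)/2) = f^(-beta0/2) * exp(b(t) * l_k) with beta0 the
    mid-ramp exponent, b(t) = (beta(t) - beta0)/1 and l_k = -ln(f_k)/2,
    the series expansion of the exponential turns the modulation into a
    sum over j of b(t)^j / j! times the inverse transform of the
    l_k^j-weighted base spectrum.  The result is normalized to unit
    variance at every t using the matching expansion of the theoretical
    variance envelope.

    ``freq_floor`` (cycles/sample) optionally flattens the spectrum
    below a cutoff: power at lower frequencies is held at the cutoff
    level.  Windowed estimators never resolve that band, while
    unbounded 1/f^beta power at multidecadal periods would dominate
    window means; the floored process keeps the imposed exponent over
    every frequency a windowed periodogram sees.
    """
    if beta_start == beta_end and freq_floor is None:
        return _colored_noise_matrix(n, beta_start, rng, n_series).astype(dtype)
    if n < 16:
        raise ValueError(f"need n >= 16, got {n}")
    if min(beta_start, beta_end) < 0:
        raise ValueError("beta must be >= 0")
    # synthesize at an FFT-friendly length and truncate
    n_fft = fft.next_fast_len(n)
    freqs = np.fft.rfftfreq(n_fft)
    f_eff = np.maximum(freqs, freq_floor) if freq_floor else freqs
    beta0 = 0.5 * (beta_start + beta_end)
    amp0 = np.zeros_like(freqs)
    amp0[1:] = f_eff[1:] ** (-beta0 / 2.0)
    ell = np.zeros_like(freqs)
    ell[1:] = -0.5 * np.log(f_eff[1:])
    b = np.linspace(beta_start - beta0, beta_end - beta0, n_fft)

    def _n_terms(z: float, tol: float = 1e-7) -> int:
        # smallest J with z^(J+1)/(J+1)! < tol (Taylor remainder of exp)
        term, j = z, 1
        while term >= tol and j < 80:
            j += 1
            term *= z / j
        return j

    zmax = float(np.max(np.abs(b)) * ell.max())
    j_field = max(4, _n_terms(zmax))
    j_env = max(j_field, _n_terms(2.0 * zmax))

    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    fdtype = np.float32 if dtype == np.float32 else np.float64
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_series, len(freqs)))
    spectrum = (amp0 * np.exp(1j * phases)).astype(cdtype)
    spectrum[:, 0] = 0.0
    if n_fft % 2 == 0:
        spectrum[:, -1] = spectrum[:, -1].real
    x = np.zeros((n_series, n_fft), dtype=dtype)
    var_env = np.zeros(n_fft)
    b_pow = np.ones(n_fft)
    amp0_sq = amp0**2
    ell_f = ell.astype(fdtype)
    for j in range(j_env + 1):
        if j <= j_field:
            x += (b_pow.astype(fdtype) * fft.irfft(spectrum * ell_f**j, n=n_fft, axis=1))
        var_env += b_pow * float(np.sum((2.0 * ell) ** j * amp0_sq))
        b_pow *= b / (j + 1)
    x /= np.sqrt(var_env / var_env.mean()).astype(fdtype)
    x = x[:, :n]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x / sd).astype(dtype)


def generate_gaussian_field(
    lats: np.ndarray,
    lons: np.ndarray,
    practical_range_km: float,
    sill: float,
    nugget: float,
    seed,
    n_fields: int = 1,
) -> np.ndarray:
    """Zero-mean Gaussian random field(s) on the cells of a lat-lon grid.

    The theoretical semivariogram is
    ``gamma(h) = nugget + sill * (1 - exp(-(h/a)^2))`` with
    ``practical_range_km = sqrt(3) * a`` and h the great-circle distance.
    Returns an array of shape (n_fields, n_lat, n_lon).
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    if glat.size < 4:
        raise ValueError("grid must have at least 4 cells")
    if practical_range_km < 0 or sill < 0 or nugget < 0:
        raise ValueError("practical_range_km, sill and nugget must be >= 0")
    if glat.size > 5000:
        raise ValueError(
            f"grid has {glat.size} cells; covariance factorization is capped at 5000"
        )
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((glat.size, n_fields))
    L = _field_factor(glat.ravel(), glon.ravel(), practical_range_km, sill, nugget)
    fields = (L @ z).T.reshape(n_fields, *glat.shape)
    return fields


def _field_factor(lat_cells, lon_cells, practical_range_km, sill, nugget):
    """Cholesky factor of the Gaussian-covariance matrix on given cells."""
    n = len(lat_cells)
    if practical_range_km == 0 or sill == 0:
        return np.sqrt(sill + nugget) * np.eye(n)
    rlat, rlon = np.radians(lat_cells), np.radians(lon_cells)
    h = _haversine(rlat[:, None], rlon[:, None], rlat[None, :], rlon[None, :])
    a = practical_range_km / np.sqrt(3.0)
    cov = sill * np.exp(-((h / a) ** 2))
    cov[np.diag_indices(n)] += nugget
    jitter = 1e-10 * (sill + nugget)
    for _ in range(8):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        "covariance matrix is numerically non-positive-definite "
        f"(range {practical_range_km} km on {n} cells)"
    )


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic model ensemble.

    beta_profile is the spectral-exponent magnitude (start, end) ramped
    linearly over the series; warming_trend is in degC per decade;
    range_change optionally imposes a step in the spatial practical
    range: (change_year, new_range_km).
    """

    n_models: int = 3
    years: tuple[int, int] = (2000, 2059)
    lats: tuple[float, ...] = tuple(np.arange(-23.75, 24.0, 2.5))
    lons: tuple[float, ...] = tuple(np.arange(-23.75, 24.0, 2.5))
    beta_profile: tuple[float, float] = (0.5, 1.5)
    spatial_practical_range_km: float = 500.0
    range_change: tuple[int, float] | None = None
    sill: float = 1.0
    nugget: float = 0.05
    noise_freq_floor: float | None = 1.0 / 3650.0
    annual_amplitude: float = 10.0
    warming_trend: float = 0.3
    base_mean: float = 15.0
    noise_sigma: float = 1.0
    outlier_rate: float = 0.0
    gap_calendar: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("end year precedes start year")
        if min(self.beta_profile) < 0:
            raise ValueError("beta_profile values must be >= 0")
        if self.sill < 0 or self.nugget < 0 or self.spatial_practical_range_km < 0:
            raise ValueError("sill, nugget and spatial range must be >= 0")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a probability")

    @property
    def calendar(self) -> str:
        return cal.NOLEAP if self.gap_calendar else cal.STANDARD

    @property
    def n_years(self) -> int:
        return self.years[1] - self.years[0] + 1


def _annual_cycle(dates: np.ndarray, amplitude: float) -> np.ndarray:
    """Annual sinusoid keyed to (month, day) so it repeats exactly every year.

    The phase uses the day's position in a fixed 365-day year (Feb 29
    shares Feb 28's value), which makes the cycle identical across leap
    and non-leap years and hence exactly removable by seasonal detrending.
    """
    month_starts = np.concatenate([[0], np.cumsum(cal.month_lengths(2001, cal.NOLEAP))])
    m, d = dates[:, 1], np.minimum(dates[:, 2], 28 + (dates[:, 1] != 2) * 3)
    doy365 = month_starts[m - 1] + d
    return amplitude * np.sin(2.0 * np.pi * (doy365 - 1) / 365.0)


def _range_for_year(spec: SynthSpec, year: int) -> float:
    if spec.range_change is not None and year >= spec.range_change[0]:
        return float(spec.range_change[1])
    return float(spec.spatial_practical_range_km)


def generate_ensemble(spec: SynthSpec) -> tuple[list[GriddedTemperature], pd.DataFrame]:
    """Generate n_models gridded daily datasets plus the ground-truth record.

    Identical specs (including seed) reproduce bit-identical output.
    """
    lats = np.asarray(spec.lats, dtype=float)
    lons = np.asarray(spec.lons, dtype=float)
    n_cells = len(lats) * len(lons)
    start = (spec.years[0], 1, 1)
    end = (spec.years[1], 12, 31)
    if spec.gap_calendar:
        n_days = cal.date_span_days(start, end, cal.NOLEAP)
    else:
        n_days = cal.date_span_days(start, end, cal.STANDARD)
    dates = cal.date_range(start, n_days, spec.calendar)
    dec_year = cal.decimal_year(dates, spec.calendar)
    cycle = _annual_cycle(dates, spec.annual_amplitude)
    trend = spec.warming_trend * (dec_year - dec_year[0]) / 10.0

    block_years = [
        spec.years[0] + i * SPATIAL_BLOCK_YEARS
        for i in range(int(np.ceil(spec.n_years / SPATIAL_BLOCK_YEARS)))
    ]
    block_of_day = np.minimum(
        (dates[:, 0] - spec.years[0]) // SPATIAL_BLOCK_YEARS, len(block_years) - 1
    )
    factors = {
        r: _field_factor(
            np.repeat(lats, len(lons)), np.tile(lons, len(lats)), r, spec.sill, spec.nugget
        )
        for r in {_range_for_year(spec, y) for y in block_years}
    }

    root = np.random.SeedSequence(spec.seed)
    model_seeds = root.spawn(spec.n_models)
    datasets: list[GriddedTemperature] = []
    truth_rows = []
    for m, ss in enumerate(model_seeds):
        rng = np.random.default_rng(ss)
        values = spec.noise_sigma * _ramped_noise_matrix(
            n_days, spec.beta_profile[0], spec.beta_profile[1], rng, n_cells,
            freq_floor=spec.noise_freq_floor, dtype=np.float32,
        ).astype(np.float64)
        for b, year in enumerate(block_years):
            L = factors[_range_for_year(spec, year)]
            field = L @ rng.standard_normal(n_cells)
            values[:, block_of_day == b] += field[:, None]
        values += spec.base_mean + trend + cycle
        if spec.outlier_rate > 0:
            mask = rng.random(values.shape) < spec.outlier_rate
            values[mask] = rng.uniform(61.0, 80.0, size=int(mask.sum()))
        data = GriddedTemperature(
            lat=lats,
            lon=lons,
            dates=dates,
            values=values.T.reshape(n_days, len(lats), len(lons)),
            calendar=spec.calendar,
        )
        datasets.append(data)
        truth_rows.append(
            {
                "model": m,
                "beta_start": spec.beta_profile[0],
                "beta_end": spec.beta_profile[1],
                "practical_range_km": spec.spatial_practical_range_km,
                "range_change_year": spec.range_change[0] if spec.range_change else np.nan,
                "range_after_change_km": spec.range_change[1] if spec.range_change else np.nan,
                "sill": spec.sill,
                "nugget": spec.nugget,
                "annual_amplitude": spec.annual_amplitude,
                "warming_trend_per_decade": spec.warming_trend,
                "noise_sigma": spec.noise_sigma,
                "outlier_rate": spec.outlier_rate,
                "calendar": spec.calendar,
                "seed": spec.seed,
            }
        )
    return datasets, pd.DataFrame(truth_rows)


def write_ensemble(datasets, truth: pd.DataFrame, outdir) -> None:
    """Write each member as CF-style NetCDF plus the ground-truth CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m, data in enumerate(datasets):
        data.to_netcdf(outdir / f"model{m:02d}.nc")
    truth.to_csv(outdir / "ground_truth.csv", index=False)
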