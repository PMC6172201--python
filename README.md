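# climautocorr

Tools for quantifying how the **temporal** and **spatial autocorrelation**
of gridded daily surface temperature change over time across an ensemble
of climate-model runs — the statistical properties of the environment
that govern ecological persistence: redder temperature noise prolongs
runs of bad conditions (eroding temporal refugia), and longer spatial
correlation ranges synchronize separated populations via the Moran
effect (eroding spatial rescue).

Given daily temperature fields for M ensemble members (CF-style NetCDF,
any of the standard / noleap / 360-day model calendars), the package:

1. **standardizes** each member — bilinear regridding to a common 1°
   grid, a real leap-year calendar with gap interpolation, removal of
   values above 60 °C;
2. computes, in consecutive multi-year windows (5–10 yr), two metrics:
   * the **spectral exponent** s of each cell's detrended daily series —
     the OLS slope of log periodogram power on log frequency, P(f) ∝ f^s;
     more negative = more low-frequency variance = stronger temporal
     autocorrelation ("reddening" = s decreasing over time);
   * the **spatial range** R of each region's temperature field — from a
     Gaussian variogram model γ(h) = c₀ + c·(1 − e^{−(h/a)²}) fitted by
     weighted least squares to the empirical semivariogram over
     great-circle lags h, reporting the practical range R = √3·a (95% of
     sill);
3. regresses each windowed metric on time by **GLS with AR(1) errors**
   (REML-profiled φ, small-sample bias correction, t-based inference)
   and summarizes the ensemble by **agreement** (fraction of members
   matching the ensemble trend's sign) and **robustness** (matching sign
   *and* individually significant at α = 0.05);
4. detects trend **breakpoints** ("tipping points") by exact
   dynamic-programming piecewise-linear segmentation (0–5 breaks,
   independent line per segment, ≥3 windows each) with small-sample
   AICc selection;
5. maps per-cell exponent trends with latitudinal/longitudinal
   summaries, and writes trend/ensemble/breakpoint tables, metric
   series, NetCDF maps and a JSON run manifest.

A first-class synthetic-data module generates model ensembles with
*known* spectral exponents (optionally drifting in time), spatial
variogram ranges (optionally stepping mid-series), annual cycles,
warming trends, calendar gaps and outliers, so every stage is testable
by parameter recovery — no multi-terabyte model archive is needed.
See `docs/methods.md` for the estimators and the testbed's assumptions.

## Worked example

```python
import numpy as np
from climautocorr import SynthSpec, generate_ensemble, multimodel_mean, gls_trend
from climautocorr.autocorr import windowed_spectral_exponents, windowed_spatial_ranges
from climautocorr.breakpoints import select_n_breaks
from climautocorr.preprocess import partition_windows

# 3 members, 60 years of daily data on a 10x10 grid; temporal noise
# reddens from beta 0.5 to 1.5; the spatial range steps 500 -> 1200 km in 2030
spec = SynthSpec(n_models=3, years=(2000, 2059), seed=1,
                 lats=tuple(np.arange(-13.5, 14.0, 3.0)),
                 lons=tuple(np.arange(-13.5, 14.0, 3.0)),
                 beta_profile=(0.5, 1.5), range_change=(2030, 1200.0))
members, truth = generate_ensemble(spec)
ensemble_mean = multimodel_mean(members)

windows = partition_windows(2000, 2059, 5)
mids = np.array([w.midpoint for w in windows])

exponents = windowed_spectral_exponents(ensemble_mean, windows)
series = np.nanmean(exponents.reshape(len(windows), -1), axis=1)
print("per-window spectral exponents:", np.round(series, 3))
print(gls_trend(series, mids).summary())

ranges = np.nanmean(np.stack([
    windowed_spatial_ranges(m, windows, seed=i)[0] for i, m in enumerate(members)
]), axis=0)
print("per-window spatial ranges (km):", np.round(ranges, 0))
print(select_n_breaks(ranges, mids).summary())
```

prints

```
per-window spectral exponents: [-0.702 -0.762 -0.843 -0.902 -0.986 -1.064 -1.163 -1.226 -1.317 -1.417
 -1.484 -1.571]
Trend fit (gls-ar1, n=12)
  slope      -0.0157886 per year  (se 0.000895)
  intercept  +30.9074
  95% CI     [-0.0177838, -0.0137935]
  p-value    7.328e-09
  AR(1) phi  +0.990
per-window spatial ranges (km): [ 508.  746.  590.  517.  437.  552. 1230. 1318. 1182. 1205. 1209. 1162.]
Piecewise linear fit: 1 break(s), n=12, RSS=55579.2, AICc=130.088
  before break 1   intercept +9554.34  slope -4.46574  p=0.436
  after break 1    intercept +8774.67  slope -3.69641  p=0.175
  break years: 2032
```

The window-mean spectral exponent drifts from −0.70 to −1.57, tracking
the imposed β ramp, and its GLS trend is strongly negative
(−0.016 yr⁻¹, p ≈ 10⁻⁸): the ensemble "reddens". The fitted spatial
range jumps from ~500 km to ~1200 km, and AICc selects exactly one
breakpoint, at 2032 — the first window after the imposed 2030 step
(window midpoints are 5 years apart). Within each regime the segment
slopes are indistinguishable from zero, as imposed.

The same analysis runs from the shell:

```sh
climautocorr synth  --spec spec.yaml --out ensemble/   # NetCDF + ground-truth CSV
climautocorr ingest --in model.nc    --out standardized/
climautocorr run    --config config.yaml               # tables, maps, manifest
```

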