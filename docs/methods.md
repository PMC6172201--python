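# Methods

`climautocorr` quantifies how two statistical properties of gridded daily
surface temperature change over time across an ensemble of climate-model
runs: its **temporal autocorrelation**, summarized by the spectral
exponent, and its **spatial autocorrelation**, summarized by the variogram
practical range. This note documents the estimators, the synthetic
testbed, the numerical choices, and the limits of what the tests show.

## Temporal autocorrelation: the spectral exponent

Each grid cell's daily series is first conditioned: missing values
(e.g. calendar-inserted Feb 29) are filled by linear interpolation in
time (edge gaps take the nearest valid value, keeping series lengths
uniform for the FFT); a single ordinary-least-squares line fitted over
the *entire* series removes the secular warming signal. Optionally the
mean annual profile — the multi-year mean for each calendar (month, day),
with Feb 29 averaged over leap years only — is subtracted as well.
Linear-only detrending retains the seasonal cycle and is the
*conservative* variant for detecting autocorrelation trends (the cycle's
high-power, low-frequency line has large leverage on the spectral slope
and is essentially constant over time); seasonal detrending is the
*anti-conservative* variant. The default is linear.

For each multi-year window, the one-sided periodogram of the windowed
segment is computed by FFT (zero frequency excluded; normalization
satisfies Parseval: the power sum times the frequency spacing equals the
segment variance). The **spectral exponent** is the OLS slope of
log-power on log-frequency over all positive-frequency bins (zero-power
bins dropped; at least 8 bins required; the slope is invariant to the
log base and to rescaling the series). More negative exponents mean
variance concentrated at low frequencies — "redder" noise, longer
environmental memory.

## Spatial autocorrelation: the variogram practical range

For each window and region (global; tropics |lat| <= 23.5°; temperate
23.5° < |lat| <= 66°), the empirical semivariogram
gamma(h) = mean of (z_i - z_j)^2 / 2 over cell pairs at great-circle
lag h (haversine, Earth radius 6371 km) is computed in 30 equal-width
bins up to half the maximum pairwise distance, with pairs subsampled
(seeded, without replacement) when they exceed a 10^6 budget. A
Gaussian variogram model

    gamma(h) = c0 + c (1 - exp(-(h/a)^2))

is fitted by weighted least squares (weights = pair counts; bounds
c0, c >= 0, a > 0 with a capped at twice the largest lag; five
data-driven starts to avoid local minima). The reported **spatial
range** is the practical range sqrt(3) a — the lag at 95% of the sill —
operationalizing "the distance at which semivariance plateaus". Fits
with no resolvable structure (partial sill ~ 0) are flagged degenerate;
fits whose practical range exceeds twice the largest observed lag are
treated as missing in windowed series, since they are pure
extrapolation beyond the domain.

The field entering each window's variogram is, by default, not a single
window aggregate: the variogram of each *year's* mean field inside the
window is computed on a shared set of pairs and bins, and the per-year
semivariances are pooled before fitting. The mean of k random fields is
itself a single field realization, so a window-mean variogram carries
irreducible one-realization noise with heavy tails; pooling averages k
independent realizations inside the variogram and is markedly more
stable on small domains. Window-mean and window-median aggregates
remain available (`aggregate="mean"/"median"`).

## Trends: GLS with AR(1) errors

Windowed metric series (metric against window midpoint year; windows of
5-10 years; consecutive, non-overlapping, trailing partial windows
dropped) are short and serially correlated. The trend model is a
straight line with AR(1) residual correlation on the window index. The
AR(1) coefficient is profiled out of the restricted (REML) Gaussian
likelihood using the Prais-Winsten transform; because the maximum
likelihood estimate of phi is biased low at these sample sizes (which
understates the slope standard error), a Kendall-type correction
phi + (1 + 3 phi)/n is applied before inference. Slope p-values and 95%
confidence intervals use a t reference with n - 2 degrees of freedom.
Fixing phi = 0 reproduces ordinary least squares exactly (this is a
tested invariant, cross-checked against statsmodels OLS); OLS is also
the automatic fallback if the profile optimization fails, flagged on
the fit. Monte-Carlo calibration under the default settings (zero-slope
AR(1) noise, phi = 0.5, n = 22 windows) gives an empirical type-I error
of ~0.06 at alpha = 0.05.

## Ensemble statistics

With M members, the ensemble-level metric series is formed in one of
two modes: **temperature-first** (the default for trend tables) computes
metrics of the cellwise multimodel-mean temperature; **metric-mean**
averages the per-model metric series. *Agreement* is the fraction of
members whose trend slope shares the sign of the ensemble trend;
*robustness* is the fraction sharing the sign and individually
significant (p < alpha, default 0.05). A member slope of exactly zero
counts against agreement (a measure-zero tie rule). Both statistics are
exact multiples of 1/M and robustness <= agreement by construction.

Breakpoint analysis of the spatial-range series uses the metric-mean
mode: a fitted range from one multimodel-mean field is a
single-realization estimate with occasional wild values, whereas the
mean of M independent per-model fits has ~sqrt(M) lighter noise and no
heavy tail, which matters greatly for residual-sum-of-squares
segmentation on ~12 points.

Per-cell maps apply the cell-level trend and ensemble statistics
independently at every grid cell (for the spectral exponent, at one
configurable window size, default 10 years), and latitudinal/
longitudinal summaries report the percentage of valid cells per
latitude (longitude) with negative/positive slopes and with
agreement/robustness above 50%.

## Breakpoints: exact segmentation with AICc selection

Changes in the linear trend ("tipping points") are detected by piecewise
linear regression: segment boundaries lie on window boundaries, each
segment holds at least 3 windows (preventing 2-point lines), and each
segment gets its own independent OLS line — deliberately disconnected
rather than a continuous spline, because the object of interest is the
local trend before/after the break and its own intercept and slope. For
a given break count (0-5) the globally RSS-optimal segmentation is found
by exact dynamic programming over boundary positions (verified against
exhaustive enumeration in the tests); ties resolve to the earliest
breaks. The break count is selected by the small-sample Akaike
criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),

with k = 2(s+1) + s + 1 parameters for s breaks (a line per segment,
the break positions, and the residual variance); candidates with
n - k - 1 <= 0 are infeasible. Alternative parameter counts (e.g.
excluding break positions) would penalize less and select more breaks;
the stated count is the package's convention. RSS values at numerical
zero are floored (1e-12 of the series' total sum of squares) so that
perfect fits are ties resolved toward fewer breaks. Note the AICc
correction term is severe at small n: at n = 12 a single break must
reduce RSS by a factor ~5 to be selected — weak regime shifts on short
series are deliberately not reported. Conversely, because the search is
exactly optimal, it capitalizes on chance more than heuristic searches:
on pure-noise 22-window series it selects a spurious break in ~13% of
replicates with the default minimum segment of 3 windows (~11% at 4,
~9% at 5, measured over 2000 replicates). Detected breaks on short
series should always be read together with their per-segment fits.

A reported break year is the time of the first window of the post-break
segment. Per-segment trend fits ("before break 1", "after break 1", ...)
use the AR(1) GLS above when a segment has >= 5 windows and OLS (flagged)
for shorter segments.

## The synthetic testbed

No real model archive is required anywhere: every estimator is validated
by parameter recovery on synthetic ensembles with known ground truth.
The generator composes, per member and cell:

* **Colored noise** with spectral exponent beta, synthesized in the
  frequency domain: amplitudes proportional to f^(-beta/2), uniform
  random phases, zero DC, unit variance — exactly the spectral model the
  estimator fits. A time-varying exponent (reddening) modulates each
  Fourier amplitude with the instantaneous target f^(-beta(t)/2)
  (evaluated via a truncated exponential-series expansion, a few dozen
  FFTs per batch of cells, with a variance envelope keeping unit
  variance at every t), so a window centred at t has local spectrum
  proportional to f^(-beta(t)) and the estimated per-window exponent
  tracks -beta(t) linearly. Ensemble noise is band-limited: power below
  1/3650 cycles/day is held at the cutoff level. Windowed periodograms
  (windows <= 10 years) never resolve that band, while unbounded
  1/f^beta power at multidecadal periods would otherwise dominate
  window-mean fields and swamp the spatial signal as an artificial
  nugget.
* **Spatially correlated anomalies**: Gaussian random fields with the
  Gaussian covariance matching the variogram model above (practical
  range sqrt(3) a, great-circle distances), drawn by Cholesky
  factorization of the cell covariance (grids capped at 5000 cells),
  redrawn independently each calendar year and held constant within it.
  An optional step change (year, new range) imposes a spatial-range
  tipping point.
* **Deterministic structure**: a constant base temperature (15 °C), a
  linear warming trend (default 0.3 °C/decade), and an annual sinusoid
  (default amplitude 10 °C) keyed to (month, day) so it repeats exactly
  across years and is exactly removable by seasonal detrending. Optional
  leap-day gaps (noleap calendar) exercise calendar standardization, and
  rare injected outliers above 60 °C exercise outlier screening.

Space and time are separable by construction (field pattern x temporal
noise); there is no true space-time covariance, no land/sea contrast,
no teleconnections, and the annual redraw of spatial fields is an
artifact of the testbed. Passing tests therefore demonstrate that the
estimators recover imposed structure of the kind and magnitude
described — not that real temperature fields satisfy these models.

Default study conditions (frozen; chosen so that the imposed effects are
comfortably detectable by the chain under test at desk-scale compute):
5 members, daily data for 2000-2059, a 20 x 20 cell grid at 2.5°
spacing centred on the equator (domain ~5300 km, several practical
ranges wide — essential for variogram identifiability), beta ramping
0.5 -> 1.5 over the 60 years, practical range 500 km stepping to
1200 km in 2030, sill 1.0 °C², nugget 0.05 °C², unit noise standard
deviation. Identical specs (including the seed) reproduce bit-identical
ensembles; the noise synthesis runs in float32 for speed, which is far
below estimator noise at these problem sizes.

The acceptance script (`scripts/acceptance.py`) re-runs the recovery
experiments at moderately reduced replicate counts (30 spectral
replicates per noise color, 10 field realizations per range, 500 GLS
calibration replicates, 30 breakpoint replicates, 8 end-to-end seeds);
the test suite uses the full counts (50/10/1000/50/20).

## Known limitations

* Regridding is NaN-aware bilinear only (no conservative/area-weighted
  option); longitudes are treated on [-180, 180) without wraparound
  interpolation across the dateline.
* The 360-day-calendar mapping (proportional within months, first write
  wins, unmapped real dates missing) is a convenience; only the noleap
  path is exercised by the generator.
* Global and regional means of per-cell exponents are unweighted by
  default (`cos`-latitude weighting is not applied); on the synthetic
  equator-centred grids the difference is negligible.
* One breakpoint method is implemented (exact RSS segmentation +
  AICc); no alternative detectors are bundled for cross-checking.
* GLS assumes AR(1) correlation on the window index with constant
  variance; no variance function is fitted.
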