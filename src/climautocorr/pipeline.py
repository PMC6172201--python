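"""End-to-end analysis pipeline and result writers.

Composes the stages — standardization, conditioning, windowed metrics,
GLS trends, ensemble agreement, breakpoints — over an ensemble of
gridded datasets (read from NetCDF or generated synthetically), for
every requested window size and region, and writes tabular outputs:

* a trend table (slope / intercept / p per window size, metric, region),
* an ensemble table (agreement / robustness),
* a breakpoint table (selected breaks and per-segment fits),
* the windowed metric series themselves,
* per-cell spectral-exponent trend maps with latitudinal/longitudinal
  summaries, and
* a JSON run manifest (config, seed, package version) for
  reproducibility: the same config and seed reproduce identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .autocorr import (
    regional_cells,
    windowed_spatial_ranges,
    windowed_spectral_exponents,
    _conditioned_matrix,
)
from .breakpoints import BreakpointModel, PiecewiseTrendModel, segment_trends
from .exceptions import ClimAutocorrError, EstimationError
from .gridio import GriddedTemperature, read_gridded_temperature, standardize
from .preprocess import WINDOW_SIZES, partition_windows
from .synth import SynthSpec, generate_ensemble
from .trends import CellTrendMaps, EnsembleSummary, cell_slope_map, ensemble_summary, latitudinal_summary

log = logging.getLogger(__name__)

METRICS = ("spectral_exponent", "spatial_range")


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one pipeline run.

    Either ``input_dir`` (a directory of NetCDF files) or ``synth`` (a
    SynthSpec) provides the ensemble.  ``ensemble_mode`` selects how the
    ensemble-level metric series is formed: "temperature-first" computes
    metrics of the multimodel-mean temperature (the convention used for
    the headline trend tables), "metric-mean" averages the per-model
    metric series.  Breakpoint analysis of the spatial range uses the
    metric-mean series, whose per-window noise is much lighter-tailed
    (see docs/methods.md).
    """

    input_dir: str | None = None
    synth: SynthSpec | None = None
    window_sizes: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    detrend: str = "linear"
    regions: tuple[str, ...] = ("global",)
    alpha: float = 0.05
    max_breaks: int = 5
    min_segment: int = 3
    ensemble_mode: str = "temperature-first"
    spatial_aggregate: str = "yearly"
    map_window_years: int | None = 10
    standardize_inputs: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synth is None):
            raise ValueError("exactly one of input_dir and synth must be given")
        if not set(self.window_sizes) <= set(WINDOW_SIZES):
            raise ValueError(f"window_sizes must be within {{5..10}}, got {self.window_sizes}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.ensemble_mode not in ("temperature-first", "metric-mean"):
            raise ValueError(f"unknown ensemble_mode {self.ensemble_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            synth = dict(raw["synth"])
            for key in ("years", "beta_profile", "range_change", "lats", "lons"):
                if key in synth and synth[key] is not None:
                    synth[key] = tuple(synth[key])
            raw["synth"] = SynthSpec(**synth)
        for key in ("window_sizes", "regions"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class WindowRegionResult:
    """All ensemble-level results for one (window size, region, metric)."""

    window_years: int
    region: str
    metric: str
    times: np.ndarray
    multimodel_series: np.ndarray
    per_model_series: np.ndarray
    ensemble: EnsembleSummary | None = None
    breakpoints: BreakpointModel | None = None
    segments: list | None = None
    error: str | None = None


@dataclass
class AnalysisResult:
    """Bundle returned by :func:`run`."""

    config: AnalysisConfig
    results: list[WindowRegionResult]
    maps: CellTrendMaps | None
    lat_summary: pd.DataFrame | None
    lon_summary: pd.DataFrame | None
    n_models: int
    errors: list[str] = field(default_factory=list)

    def get(self, window_years: int, region: str, metric: str) -> WindowRegionResult:
        for r in self.results:
            if (r.window_years, r.region, r.metric) == (window_years, region, metric):
                return r
        raise KeyError((window_years, region, metric))


def _load_ensemble(config: AnalysisConfig) -> list[GriddedTemperature]:
    if config.synth is not None:
        datasets, _ = generate_ensemble(config.synth)
    else:
        paths = sorted(Path(config.input_dir).glob("*.nc"))
        if not paths:
            raise ClimAutocorrError(f"no NetCDF files found in {config.input_dir}")
        datasets = [read_gridded_temperature(p) for p in paths]
    if config.standardize_inputs and config.synth is None:
        datasets = [standardize(d) for d in datasets]
    return datasets


def _regional_mean_series(exponents: np.ndarray, lat: np.ndarray, lon: np.ndarray, region: str) -> np.ndarray:
    glat, _ = np.meshgrid(lat, lon, indexing="ij")
    mask = regional_cells(glat.ravel(), region)
    flat = exponents.reshape(exponents.shape[0], -1)[:, mask]
    with np.errstate(invalid="ignore"):
        return np.nanmean(flat, axis=1)


def run(config: AnalysisConfig) -> AnalysisResult:
    """Execute the full analysis; stage failures are recorded, not fatal."""
    from .trends import multimodel_mean

    datasets = _load_ensemble(config)
    mm = multimodel_mean(datasets)
    years = mm.years
    start_year, end_year = int(years.min()), int(years.max())
    errors: list[str] = []
    results: list[WindowRegionResult] = []

    # conditioned matrices are reused across window sizes
    cond_cache: dict[int, np.ndarray] = {}

    def conditioned(idx: int, data: GriddedTemperature) -> np.ndarray:
        if idx not in cond_cache:
            cond_cache[idx] = _conditioned_matrix(data, config.detrend)
        return cond_cache[idx]

    seed_root = np.random.SeedSequence(config.seed)
    spatial_seeds = seed_root.spawn(len(datasets) + 1)

    for wy in sorted(config.window_sizes):
        windows = partition_windows(start_year, end_year, wy)
        times = np.array([w.midpoint for w in windows])
        # per-model and multimodel windowed exponents
        exp_models = [
            windowed_spectral_exponents(d, windows, conditioned=conditioned(i, d))
            for i, d in enumerate(datasets)
        ]
        exp_mm = windowed_spectral_exponents(mm, windows, conditioned=conditioned(-1, mm))
        for region in config.regions:
            # --- temporal autocorrelation metric -----------------------
            per_model = np.stack(
                [_regional_mean_series(e, mm.lat, mm.lon, region) for e in exp_models]
            )
            if config.ensemble_mode == "temperature-first":
                mm_series = _regional_mean_series(exp_mm, mm.lat, mm.lon, region)
            else:
                mm_series = np.nanmean(per_model, axis=0)
            results.append(
                _analyze_series(
                    config, wy, region, "spectral_exponent", times, mm_series, per_model, errors
                )
            )
            # --- spatial autocorrelation metric ------------------------
            try:
                per_model_sr = np.stack(
                    [
                        windowed_spatial_ranges(
                            d, windows, region=region, aggregate=config.spatial_aggregate,
                            seed=spatial_seeds[i],
                        )[0]
                        for i, d in enumerate(datasets)
                    ]
                )
                if config.ensemble_mode == "temperature-first":
                    mm_sr = windowed_spatial_ranges(
                        mm, windows, region=region, aggregate=config.spatial_aggregate,
                        seed=spatial_seeds[-1],
                    )[0]
                else:
                    with np.errstate(invalid="ignore"):
                        mm_sr = np.nanmean(per_model_sr, axis=0)
                results.append(
                    _analyze_series(
                        config, wy, region, "spatial_range", times, mm_sr, per_model_sr, errors
                    )
                )
            except (ClimAutocorrError, ValueError) as exc:
                errors.append(f"spatial_range w={wy} region={region}: {exc}")

    maps = lat_sum = lon_sum = None
    if config.map_window_years is not None and config.map_window_years in config.window_sizes:
        try:
            windows = partition_windows(start_year, end_year, config.map_window_years)
            times = np.array([w.midpoint for w in windows])
            exp_models = np.stack(
                [
                    windowed_spectral_exponents(d, windows, conditioned=conditioned(i, d))
                    for i, d in enumerate(datasets)
                ]
            )
            exp_mm = windowed_spectral_exponents(mm, windows, conditioned=conditioned(-1, mm))
            maps = cell_slope_map(exp_models, exp_mm, times, mm.lat, mm.lon, alpha=config.alpha)
            lat_sum = latitudinal_summary(maps, "lat")
            lon_sum = latitudinal_summary(maps, "lon")
        except (ClimAutocorrError, ValueError) as exc:
            errors.append(f"cell maps: {exc}")

    result = AnalysisResult(
        config=config, results=results, maps=maps,
        lat_summary=lat_sum, lon_summary=lon_sum,
        n_models=len(datasets), errors=errors,
    )
    if config.output_dir is not None:
        write_results(result, config.output_dir)
    return result


def _analyze_series(config, wy, region, metric, times, mm_series, per_model, errors):
    res = WindowRegionResult(
        window_years=wy, region=region, metric=metric, times=times,
        multimodel_series=mm_series, per_model_series=per_model,
    )
    keep = np.isfinite(mm_series)
    try:
        res.ensemble = ensemble_summary(per_model[:, keep], mm_series[keep], times[keep], config.alpha)
    except (EstimationError, ValueError) as exc:
        res.error = f"trend: {exc}"
        errors.append(f"{metric} w={wy} region={region}: {exc}")
        return res
    try:
        model = PiecewiseTrendModel(
            mm_series[keep], times[keep],
            max_breaks=config.max_breaks, min_segment=config.min_segment,
        )
        res.breakpoints = model.fit()
        if res.breakpoints.n_breaks > 0:
            res.segments = segment_trends(mm_series[keep], times[keep], res.breakpoints.break_years)
    except (EstimationError, ValueError) as exc:
        errors.append(f"breakpoints {metric} w={wy} region={region}: {exc}")
    return res


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------

def _trend_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for r in result.results:
        if r.ensemble is None:
            continue
        fit = r.ensemble.reference_fit
        rows.append(
            {
                "window_years": r.window_years, "region": r.region, "metric": r.metric,
                "slope": fit.slope, "intercept": fit.intercept, "p_value": fit.p_value,
                "ar1_phi": fit.ar1_phi, "n_windows": fit.n_windows, "method": fit.method,
            }
        )
    return pd.DataFrame(rows)


def _ensemble_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for r in result.results:
        if r.ensemble is None:
            continue
        rows.append(
            {
                "window_years": r.window_years, "region": r.region, "metric": r.metric,
                "agreement": r.ensemble.agreement, "robustness": r.ensemble.robustness,
                "n_models": r.ensemble.n_models,
            }
        )
    return pd.DataFrame(rows)


def _breakpoint_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for r in result.results:
        if r.breakpoints is None:
            continue
        row = {
            "window_years": r.window_years, "region": r.region, "metric": r.metric,
            "n_breaks": r.breakpoints.n_breaks, "aicc": r.breakpoints.aicc,
        }
        for b_i, (b0, b1, p) in enumerate(r.breakpoints.segments):
            tag = "before_break_1" if b_i == 0 else f"after_break_{b_i}"
            row[f"{tag}_intercept"] = b0
            row[f"{tag}_slope"] = b1
            row[f"{tag}_significant"] = p < result.config.alpha
            if b_i < r.breakpoints.n_breaks:
                row[f"break_{b_i + 1}_year"] = r.breakpoints.break_years[b_i]
        rows.append(row)
    return pd.DataFrame(rows)


def _series_table(result: AnalysisResult) -> pd.DataFrame:
    rows = []
    for r in result.results:
        for t, v in zip(r.times, r.multimodel_series):
            rows.append(
                {
                    "window_years": r.window_years, "region": r.region, "metric": r.metric,
                    "model": "ensemble", "window_midpoint": t, "value": v,
                }
            )
        for m_i, series in enumerate(r.per_model_series):
            for t, v in zip(r.times, series):
                rows.append(
                    {
                        "window_years": r.window_years, "region": r.region, "metric": r.metric,
                        "model": f"model{m_i:02d}", "window_midpoint": t, "value": v,
                    }
                )
    return pd.DataFrame(rows)


def write_results(result: AnalysisResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _trend_table(result).to_csv(outdir / "trends.csv", index=False)
    _ensemble_table(result).to_csv(outdir / "ensemble.csv", index=False)
    _breakpoint_table(result).to_csv(outdir / "breakpoints.csv", index=False)
    _series_table(result).to_csv(outdir / "metric_series.csv", index=False)
    if result.maps is not None:
        result.maps.to_xarray().to_netcdf(outdir / "spectral_exponent_maps.nc", engine="scipy")
        result.lat_summary.to_csv(outdir / "latitudinal_summary.csv", index=False)
        result.lon_summary.to_csv(outdir / "longitudinal_summary.csv", index=False)
    from . import __version__ as version

    manifest = {
        "package": "climautocorr",
        "version": version,
        "seed": result.config.seed,
        "n_models": result.n_models,
        "errors": result.errors,
        "config": _config_dict(result.config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synth is not None:
        d["synth"] = dataclasses.asdict(config.synth)
    return d
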