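"""Quick-look plots for windowed metric series and trend maps."""

from __future__ import annotations

import numpy as np


def plot_metric_series(result, ax=None):
    """Windowed metric series with its GLS trend line and breakpoint segments.

    `result` is a :class:`climautocorr.pipeline.WindowRegionResult`.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t, v = result.times, result.multimodel_series
    for series in result.per_model_series:
        ax.plot(t, series, color="0.8", lw=0.7, zorder=1)
    ax.plot(t, v, "o-", color="k", lw=1.5, ms=4, zorder=3, label="ensemble")
    if result.ensemble is not None:
        fit = result.ensemble.reference_fit
        style = "-" if fit.significant else "--"
        ax.plot(t, fit.predict(t), style, color="C3", zorder=2,
                label=f"GLS slope {fit.slope:+.4g}/yr (p={fit.p_value:.3g})")
    if result.breakpoints is not None and result.breakpoints.n_breaks:
        edges = [t.min(), *result.breakpoints.break_years, t.max() + 1e-9]
        for (b0, b1, p), lo, hi in zip(result.breakpoints.segments, edges[:-1], edges[1:]):
            seg_t = np.linspace(lo, hi, 8)
            ax.plot(seg_t, b0 + b1 * seg_t, "-" if p < 0.05 else "--", color="C0", zorder=2)
        for by in result.breakpoints.break_years:
            ax.axvline(by, color="C0", ls=":", lw=0.8)
    ax.set_xlabel("window midpoint (year)")
    ax.set_ylabel(result.metric.replace("_", " "))
    ax.set_title(f"{result.region}, {result.window_years}-year windows")
    ax.legend(fontsize=8)
    return ax


def plot_slope_map(maps, field: str = "slope", ax=None):
    """Plate-carree quick-look of a per-cell map (slope/p_value/agreement/robustness)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = getattr(maps, field)
    cmap = "RdBu" if field == "slope" else "viridis"
    mesh = ax.pcolormesh(maps.lon, maps.lat, data, cmap=cmap, shading="nearest")
    plt.colorbar(mesh, ax=ax, label=field)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    return ax
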