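import numpy as np
import pytest

from climautocorr import GriddedTemperature, SynthSpec, generate_ensemble
from climautocorr import calendars as cal


@pytest.fixture(scope="session")
def tiny_ensemble():
    """3 small synthetic members, 30 years, with an imposed reddening and
    a mid-series spatial-range step; shared across pipeline-level tests."""
    spec = SynthSpec(
        n_models=3,
        years=(2000, 2029),
        lats=tuple(np.arange(-13.5, 14.0, 3.0)),
        lons=tuple(np.arange(-13.5, 14.0, 3.0)),
        beta_profile=(0.5, 1.5),
        range_change=(2015, 1200.0),
        seed=42,
    )
    datasets, truth = generate_ensemble(spec)
    return spec, datasets, truth


def make_grid(values: np.ndarray, lat=None, lon=None, start=(2000, 1, 1), calendar=cal.STANDARD):
    """GriddedTemperature from a (time, lat, lon) value array."""
    nt, nlat, nlon = values.shape
    lat = np.arange(nlat, dtype=float) if lat is None else np.asarray(lat, float)
    lon = np.arange(nlon, dtype=float) if lon is None else np.asarray(lon, float)
    dates = cal.date_range(start, nt, calendar)
    return GriddedTemperature(lat=lat, lon=lon, dates=dates, values=values, calendar=calendar)
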