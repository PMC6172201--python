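"""Spectral exponent, great-circle distances, variograms, regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from climautocorr.autocorr import (
    EmpiricalVariogram,
    GaussianVariogramModel,
    SpectralExponentModel,
    empirical_variogram,
    fit_gaussian_variogram,
    great_circle_km,
    periodogram,
    regional_cells,
    spectral_exponent,
)
from climautocorr.exceptions import EstimationError


class TestPeriodogram:
    def test_constant_series_zero_power(self):
        _, power = periodogram(np.full(64, 3.0))
        np.testing.assert_allclose(power, 0.0, atol=1e-20)

    def test_sinusoid_concentrates_power(self):
        n = 512
        t = np.arange(n)
        f0 = 8 / n
        freqs, power = periodogram(3.0 * np.sin(2 * np.pi * f0 * t))
        assert freqs[np.argmax(power)] == pytest.approx(f0)
        assert power.max() > 1e3 * np.median(power[power > 0]) if (power > 0).sum() > 1 else True
        # all variance sits in that single bin (Parseval)
        df = freqs[1] - freqs[0]
        assert power.max() * df == pytest.approx(3.0**2 / 2, rel=1e-9)

    def test_parseval(self):
        rng = np.random.default_rng(11)
        x = rng.normal(2.0, 3.0, 1000)
        freqs, power = periodogram(x)
        df = freqs[1] - freqs[0]
        assert np.sum(power) * df == pytest.approx(x.var(), rel=0.01)

    def test_missing_values_rejected(self):
        x = np.ones(64)
        x[5] = np.nan
        with pytest.raises(ValueError):
            periodogram(x)


class TestSpectralExponent:
    def test_exact_power_law(self):
        freqs = np.linspace(0.01, 0.5, 100)
        fit = spectral_exponent(freqs, freqs**-2.0)
        assert fit.exponent == pytest.approx(-2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_flat(self):
        rng = np.random.default_rng(4)
        fit = SpectralExponentModel(rng.standard_normal(4096)).fit()
        assert abs(fit.exponent) < 0.15

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2048)
        f1 = SpectralExponentModel(x).fit()
        f2 = SpectralExponentModel(10.0 * x).fit()
        assert f2.exponent == pytest.approx(f1.exponent, abs=1e-10)
        assert f2.intercept - f1.intercept == pytest.approx(2 * np.log(10.0), abs=1e-9)

    def test_too_few_bins(self):
        with pytest.raises(EstimationError):
            spectral_exponent(np.linspace(0.1, 0.5, 5), np.ones(5))


class TestGreatCircle:
    def test_reference_distances(self):
        assert great_circle_km((0, 0), (0, 0)) == 0.0
        assert great_circle_km((0, 0), (0, 90)) == pytest.approx(np.pi * 6371 / 2, abs=0.01)
        assert great_circle_km((0, 0), (0, 180)) == pytest.approx(np.pi * 6371, abs=0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        lat=st.tuples(*[st.floats(-89, 89) for _ in range(3)]),
        lon=st.tuples(*[st.floats(-180, 179) for _ in range(3)]),
    )
    def test_symmetry_and_triangle(self, lat, lon):
        p = list(zip(lat, lon))
        d01 = great_circle_km(p[0], p[1])
        assert d01 == pytest.approx(great_circle_km(p[1], p[0]), abs=1e-9)
        d02, d12 = great_circle_km(p[0], p[2]), great_circle_km(p[1], p[2])
        assert d01 <= d02 + d12 + 1e-6


class TestEmpiricalVariogram:
    def _coords(self, n=8):
        lat, lon = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
        return lat.ravel(), lon.ravel()

    def test_constant_field_zero(self):
        lat, lon = self._coords()
        vg = empirical_variogram(np.full(64, 5.0), lat, lon, n_bins=10)
        np.testing.assert_allclose(vg.semivariance, 0.0, atol=1e-20)

    def test_iid_noise_pure_nugget(self):
        rng = np.random.default_rng(6)
        lat, lon = self._coords(20)
        field = rng.normal(0, np.sqrt(2.0), 400)
        vg = empirical_variogram(field, lat, lon, n_bins=8)
        dense = vg.pair_counts >= 200
        np.testing.assert_allclose(vg.semivariance[dense], 2.0, rtol=0.25)

    def test_too_few_cells(self):
        with pytest.raises(EstimationError):
            empirical_variogram(np.ones(10), np.arange(10.0), np.zeros(10))

    def test_pair_budget_deterministic(self):
        rng = np.random.default_rng(7)
        lat, lon = self._coords(15)
        field = rng.standard_normal(225)
        a = empirical_variogram(field, lat, lon, pair_budget=500, seed=3)
        b = empirical_variogram(field, lat, lon, pair_budget=500, seed=3)
        np.testing.assert_array_equal(a.semivariance, b.semivariance)


class TestGaussianVariogramFit:
    def test_noiseless_self_consistency(self):
        h = np.linspace(50, 3000, 20)
        gamma = 0.1 + 0.9 * (1 - np.exp(-((h / 800.0) ** 2)))
        vg = EmpiricalVariogram(h, gamma, np.full(20, 100.0), 3000.0)
        fit = fit_gaussian_variogram(vg)
        assert fit.nugget == pytest.approx(0.1, rel=1e-3)
        assert fit.partial_sill == pytest.approx(0.9, rel=1e-3)
        assert fit.shape == pytest.approx(800.0, rel=1e-3)
        assert fit.practical_range == pytest.approx(1385.64, abs=0.01)

    def test_flat_variogram_degenerate(self):
        h = np.linspace(50, 3000, 15)
        vg = EmpiricalVariogram(h, np.full(15, 2.0), np.full(15, 50.0), 3000.0)
        fit = fit_gaussian_variogram(vg)
        assert fit.is_degenerate

    def test_perturbed_recovery_within_10pct(self):
        rng = np.random.default_rng(8)
        h = np.linspace(100, 6000, 25)
        a_true = 2000.0
        gamma = 0.05 + 1.0 * (1 - np.exp(-((h / a_true) ** 2)))
        gamma *= 1 + 0.05 * rng.standard_normal(25)
        vg = EmpiricalVariogram(h, gamma, np.full(25, 100.0), 6000.0)
        fit = fit_gaussian_variogram(vg)
        assert fit.practical_range == pytest.approx(np.sqrt(3) * a_true, rel=0.10)

    def test_fitted_model_monotone_and_95pct_rule(self):
        h = np.linspace(50, 3000, 20)
        gamma = 0.2 + 1.5 * (1 - np.exp(-((h / 600.0) ** 2)))
        fit = fit_gaussian_variogram(EmpiricalVariogram(h, gamma, np.full(20, 10.0), 3000.0))
        hh = np.linspace(0, 5000, 200)
        assert np.all(np.diff(fit(hh)) >= -1e-12)
        assert fit(fit.practical_range) >= fit.nugget + 0.95 * fit.partial_sill - 1e-9


class TestRegions:
    @pytest.mark.parametrize(
        "lat,region,expected",
        [
            (0.0, "tropics", True), (0.0, "temperate", False),
            (45.0, "temperate", True), (45.0, "tropics", False),
            (70.0, "tropics", False), (70.0, "temperate", False),
            (-30.0, "temperate", True), (23.5, "tropics", True),
        ],
    )
    def test_band_membership(self, lat, region, expected):
        assert regional_cells(np.array([lat]), region)[0] == expected

    def test_global_includes_all(self):
        lats = np.array([-90.0, -45.0, 0.0, 66.5, 90.0])
        assert regional_cells(lats, "global").all()

    def test_unknown_region(self):
        with pytest.raises(ValueError):
            regional_cells(np.array([0.0]), "polar")
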