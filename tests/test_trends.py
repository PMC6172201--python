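"""GLS trends, ensemble agreement/robustness, maps and summaries."""

import numpy as np
import pytest
import statsmodels.api as sm

from climautocorr.trends import (
    CellTrendMaps,
    TrendGLS,
    cell_slope_map,
    ensemble_summary,
    gls_trend,
    latitudinal_summary,
    multimodel_mean,
)

from conftest import make_grid


def ar1_series(rng, n, phi, slope=0.0, sigma=1.0):
    e = np.empty(n)
    e[0] = rng.standard_normal() * sigma / np.sqrt(1 - phi**2)
    for i in range(1, n):
        e[i] = phi * e[i - 1] + sigma * rng.standard_normal()
    return slope * np.arange(n) + e


class TestTrendGLS:
    def test_noiseless_line_exact(self):
        t = np.arange(22.0)
        fit = gls_trend(0.5 * t + 2.0, t)
        assert fit.slope == pytest.approx(0.5, abs=1e-8)
        assert fit.intercept == pytest.approx(2.0, abs=1e-8)
        assert fit.p_value < 1e-12
        assert fit.ci95[0] <= fit.slope <= fit.ci95[1]

    def test_phi_zero_equals_statsmodels_ols(self):
        rng = np.random.default_rng(12)
        t = np.arange(22.0)
        y = ar1_series(rng, 22, 0.4, slope=0.1)
        mine = TrendGLS(y, t).fit(phi=0.0)
        X = sm.add_constant(t)
        ols = sm.OLS(y, X).fit()
        assert mine.slope == pytest.approx(ols.params[1], abs=1e-8)
        assert mine.intercept == pytest.approx(ols.params[0], abs=1e-8)
        assert mine.slope_se == pytest.approx(ols.bse[1], abs=1e-8)
        assert mine.p_value == pytest.approx(ols.pvalues[1], abs=1e-8)

    def test_positive_autocorrelation_detected(self):
        rng = np.random.default_rng(13)
        hits = [TrendGLS(ar1_series(rng, 40, 0.6), np.arange(40.0)).fit().ar1_phi for _ in range(20)]
        assert np.mean(hits) > 0.3

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            gls_trend(np.arange(4.0), np.arange(4.0))

    def test_nan_windows_dropped(self):
        t = np.arange(10.0)
        y = 2.0 * t
        y[3] = np.nan
        fit = gls_trend(y, t)
        assert fit.n_windows == 9
        assert fit.slope == pytest.approx(2.0, abs=1e-8)


class TestMultimodelMean:
    def test_cellwise_mean(self):
        a = make_grid(np.full((30, 2, 2), 10.0))
        b = make_grid(np.full((30, 2, 2), 20.0))
        np.testing.assert_allclose(multimodel_mean([a, b]).values, 15.0)

    def test_missing_cells_average_available(self):
        va = np.full((30, 1, 1), 10.0)
        va[0] = np.nan
        a, b = make_grid(va), make_grid(np.full((30, 1, 1), 30.0))
        mm = multimodel_mean([a, b])
        assert mm.values[0, 0, 0] == 30.0
        assert mm.values[1, 0, 0] == 20.0

    def test_single_model_identity(self):
        a = make_grid(np.zeros((30, 1, 1)))
        assert multimodel_mean([a]) is a

    def test_grid_mismatch_rejected(self):
        a = make_grid(np.zeros((30, 2, 2)))
        b = make_grid(np.zeros((30, 2, 2)), lat=[5.0, 6.0])
        with pytest.raises(ValueError):
            multimodel_mean([a, b])


def _member(slope, noise_amp, rng, n=22):
    """Line of known slope plus noise orthogonalized against [1, t]:
    the OLS slope is exactly `slope` while the noise only widens its
    standard error, so sign and (in)significance can be prescribed."""
    t = np.arange(float(n))
    X = np.column_stack([np.ones(n), t])
    noise = noise_amp * rng.standard_normal(n)
    noise -= X @ np.linalg.lstsq(X, noise, rcond=None)[0]
    return slope * t + noise


class TestEnsembleSummary:
    def test_exact_fractions_21_members(self):
        # 14 members share the (negative) reference sign, 2 of them significant
        rng = np.random.default_rng(21)
        t = np.arange(22.0)
        members = []
        members += [_member(-1.0, 0.01, rng) for _ in range(2)]    # same sign, significant
        members += [_member(-0.05, 2.0, rng) for _ in range(12)]   # same sign, not significant
        members += [_member(+1.0, 0.01, rng) for _ in range(7)]    # opposite sign
        summ = ensemble_summary(np.array(members), -0.5 * t, t)
        # construction sanity: each member behaves as prescribed
        signs = [f.slope < 0 for f in summ.per_model_fits]
        assert signs == [True] * 14 + [False] * 7
        sig = [f.p_value < 0.05 for f in summ.per_model_fits[:14]]
        assert sig == [True, True] + [False] * 12
        assert summ.reference_sign == -1
        assert summ.agreement == pytest.approx(14 / 21, abs=1e-12)
        assert summ.robustness == pytest.approx(2 / 21, abs=1e-12)
        # the printed two-decimal values of the fractions
        assert f"{summ.agreement:.2f}" == "0.67"
        assert round(summ.robustness, 3) == 0.095

    def test_identical_members(self):
        t = np.arange(22.0)
        y = 0.3 * t + np.sin(t)
        summ = ensemble_summary(np.tile(y, (5, 1)), y, t)
        assert summ.agreement == 1.0
        assert summ.robustness == (1.0 if summ.reference_fit.p_value < 0.05 else 0.0)

    def test_robustness_never_exceeds_agreement(self):
        rng = np.random.default_rng(30)
        t = np.arange(22.0)
        for _ in range(5):
            members = rng.standard_normal((7, 22)) + 0.05 * t
            summ = ensemble_summary(members, members.mean(axis=0), t)
            assert summ.robustness <= summ.agreement
            assert (summ.agreement * 7) == pytest.approx(round(summ.agreement * 7))


class TestMapsAndSummaries:
    def _metric_stack(self, slopes, n_models=3, n_windows=8):
        """per-model/multimodel metric arrays with prescribed per-cell slopes."""
        t = np.arange(float(n_windows))
        base = slopes[None, :, :] * t[:, None, None]
        per_model = np.stack([base + 0.001 * (m + 1) for m in range(n_models)])
        return per_model, base

    def test_imposed_signs_recovered(self):
        lat = np.arange(-2.0, 3.0)
        lon = np.arange(4.0)
        slopes = np.fromfunction(lambda i, j: np.where(i < 2, -0.5, 0.5), (5, 4))
        per_model, mm = self._metric_stack(slopes)
        maps = cell_slope_map(per_model, mm, np.arange(8.0), lat, lon)
        assert np.all(np.sign(maps.slope) == np.sign(slopes))
        assert np.all(maps.agreement == 1.0)

    def test_latitudinal_percentages(self):
        lat = np.arange(3.0)
        lon = np.arange(4.0)
        slope = np.array([[-1.0] * 4, [-1.0, -1.0, 1.0, 1.0], [1.0] * 4])
        maps = CellTrendMaps(
            lat=lat, lon=lon, slope=slope, p_value=np.full((3, 4), 0.5),
            agreement=np.full((3, 4), 0.4), robustness=np.full((3, 4), 0.2),
        )
        df = latitudinal_summary(maps, "lat")
        assert df.pct_negative_slope.tolist() == [100.0, 50.0, 0.0]
        assert df.pct_positive_slope.tolist() == [0.0, 50.0, 100.0]
        assert df.pct_agreement_gt50.tolist() == [0.0, 0.0, 0.0]

    def test_missing_latitude_is_nan(self):
        maps = CellTrendMaps(
            lat=np.arange(2.0), lon=np.arange(2.0),
            slope=np.array([[np.nan, np.nan], [1.0, -1.0]]),
            p_value=np.full((2, 2), 0.5), agreement=np.full((2, 2), 1.0),
            robustness=np.full((2, 2), 0.0),
        )
        df = latitudinal_summary(maps, "lat")
        assert np.isnan(df.pct_negative_slope[0])
        assert df.n_cells.tolist() == [0, 2]
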