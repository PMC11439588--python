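"""P-I model functions, binned fits, the temperature-modified model and Ic."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from kelpmetab import pi_models as pm

LOW = dict(pmax=26.58, alpha=0.551, cr=-5.049)  # low-bin published fit
TABLE2 = dict(pmax=22.00, alpha=0.420, rd=1.418)  # aggregate-model fit


class TestPiModel:
    def test_dark_value_is_cr(self):
        assert pm.pi_model(0.0, 10.0, 0.3, -4.0) == pytest.approx(-4.0)

    def test_saturates_at_pmax_plus_cr(self):
        assert pm.pi_model(1e6, 10.0, 0.3, -4.0) == pytest.approx(6.0)

    def test_published_low_bin_coefficients_at_100(self):
        got = pm.pi_model(100.0, LOW["pmax"], LOW["alpha"], LOW["cr"])
        want = 26.58 * math.tanh(0.551 * 100 / 26.58) - 5.049  # independent
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(20.70, abs=0.01)

    def test_strictly_increasing_and_bounded(self):
        I = np.linspace(0, 500, 200)
        y = pm.pi_model(I, 20.0, 0.4, -5.0)
        assert (np.diff(y) > 0).all()
        assert (y <= 15.0).all()


class TestTempModel:
    def test_zero_temperature_asymptote(self):
        got = pm.temp_model(1e7, 0.0, 22.0, 0.4, 1.4)
        assert got == pytest.approx(22.0 + 1.4)

    def test_published_aggregate_coefficients(self):
        got = pm.temp_model(100.0, 8.0, **{k: v for k, v in
                                           zip(("pmax", "alpha", "rd"),
                                               TABLE2.values())})
        want = (22.0 - 8.0) * math.tanh((0.42 * 100 - 8.0) / 22.0) + 1.418
        assert got == pytest.approx(want, rel=1e-12)
        assert got == pytest.approx(14.20, abs=0.01)

    def test_monotone_nonincreasing_in_temperature(self):
        for I in (20.0, 60.0, 120.0, 300.0):
            T = np.linspace(0.0, 14.0, 60)
            y = pm.temp_model(I, T, 22.0, 0.42, 1.418)
            assert (np.diff(y) <= 1e-12).all()

    def test_warming_raises_saturating_irradiance(self):
        """Half-saturation irradiance increases with temperature under the
        shifted reading -- the qualitative behaviour that selects it."""
        def half_sat(T):
            lo = pm.temp_model(0.0, T, 22.0, 0.42, 0.0)
            hi = 22.0 - T
            return optimize.brentq(
                lambda I: pm.temp_model(I, T, 22.0, 0.42, 0.0)
                - (lo + 0.9 * (hi - lo)), 0, 5000)
        assert half_sat(12.0) > half_sat(4.0)

    def test_reduced_interpretation_available(self):
        got = pm.temp_model(100.0, 8.0, 22.0, 0.42, 1.418,
                            interpretation="reduced")
        want = 14.0 * math.tanh(0.42 * 100 / 14.0) + 1.418
        assert got == pytest.approx(want, rel=1e-12)
        with pytest.raises(ValueError):
            pm.temp_model(1.0, 1.0, 22.0, 0.4, 0.0, interpretation="banana")


class TestPICurveFit:
    def test_zero_noise_recovery_both_variants(self):
        I = np.linspace(5, 160, 40)
        y = pm.pi_model(I, **{k: v for k, v in zip(("pmax", "alpha", "cr"),
                                                   LOW.values())})
        for robust in (False, True):
            fit = pm.PICurve(y, I).fit(robust=robust)
            got = fit.params.to_numpy()
            want = np.array(list(LOW.values()))
            assert np.max(np.abs(got - want) / np.abs(want)) < 1e-6
        y2 = 9.07 * np.tanh(0.091 * I / 9.07)
        fit2 = pm.PICurve(y2, I, include_respiration=False).fit()
        assert fit2.params["Pmax"] == pytest.approx(9.07, rel=1e-6)
        assert fit2.params["alpha"] == pytest.approx(0.091, rel=1e-6)

    def test_minimum_sample_sizes_enforced(self):
        with pytest.raises(ValueError, match="at least 5"):
            pm.PICurve([1, 2, 3, 4], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="at least 3"):
            pm.PICurve([1, 2], [1, 2], include_respiration=False)

    def test_robust_resists_gross_outlier(self, rng):
        """With one gross outlier injected, the robust fit moves less than
        the plain fit (vs the clean-data fit) in >= 95 of 100 seeds."""
        truth = np.array(list(LOW.values()))
        wins = 0
        for _ in range(100):
            I = rng.uniform(2, 160, 34)
            y = pm.pi_model(I, *truth) + rng.normal(0, 1.0, 34)
            base = pm.PICurve(y, I).fit(robust=False).params.to_numpy()
            y_out = y.copy()
            y_out[rng.integers(0, 34)] += 25.0
            fr = pm.PICurve(y_out, I).fit(robust=True).params.to_numpy()
            fp = pm.PICurve(y_out, I).fit(robust=False).params.to_numpy()
            wins += (np.linalg.norm((fr - base) / truth)
                     < np.linalg.norm((fp - base) / truth))
        assert wins >= 95

    def test_summary_mentions_bin_and_params(self):
        I = np.linspace(5, 160, 40)
        y = pm.pi_model(I, 20.0, 0.4, -5.0)
        fit = pm.PICurve(y, I, bin=pm.DEFAULT_BINS[0]).fit()
        text = fit.summary()
        assert "low" in text and "Pmax" in text and "Ic" in text


class TestCompensationIrradiance:
    def test_matches_numeric_root_of_curve(self):
        I = np.linspace(5, 160, 40)
        y = pm.pi_model(I, **{k: v for k, v in zip(("pmax", "alpha", "cr"),
                                                   LOW.values())})
        fit = pm.PICurve(y, I).fit()
        ic, se = fit.compensation_irradiance()
        root = optimize.brentq(lambda x: fit.predict(x), 1e-9, 1e4,
                               xtol=1e-12)
        assert ic == pytest.approx(root, abs=1e-9)
        assert ic == pytest.approx(9.276, abs=1e-2)
        assert abs(fit.predict(ic)) < 1e-9

    def test_zero_cr_gives_zero_ic(self):
        I = np.linspace(5, 160, 40)
        fit = pm.PICurve(pm.pi_model(I, 20.0, 0.4, 0.0), I).fit(robust=False)
        ic, se = fit.compensation_irradiance()
        assert ic == pytest.approx(0.0, abs=1e-6)

    def test_positive_cr_reported_missing(self):
        I = np.linspace(5, 160, 40)
        fit = pm.PICurve(pm.pi_model(I, 20.0, 0.4, 2.0), I).fit(robust=False)
        ic, se = fit.compensation_irradiance()
        assert math.isnan(ic)


class TestTemperatureModelFit:
    def _design(self, rng, n=171):
        I = rng.uniform(2, 160, n)
        T = rng.uniform(7.5, 13.5, n)
        return I, T

    def test_zero_noise_exact_recovery(self, rng):
        I, T = self._design(rng)
        y = pm.temp_model(I, T, *TABLE2.values())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pm.TemperaturePICurve(y, I, T).fit()
        want = np.array(list(TABLE2.values()))
        assert np.max(np.abs(fit.params.to_numpy() - want) / want) < 1e-6

    def test_precondition_needs_temperature_spread(self, rng):
        I = rng.uniform(2, 160, 30)
        y = np.ones(30)
        with pytest.raises(ValueError, match="span"):
            pm.TemperaturePICurve(y, I, np.full(30, 8.0))
        with pytest.raises(ValueError, match="at least 10"):
            pm.TemperaturePICurve(y[:5], I[:5], np.linspace(7, 14, 5))

    def test_insignificant_rd_warns(self, rng):
        I, T = self._design(rng)
        y = pm.temp_model(I, T, 22.0, 0.42, 0.0) + rng.normal(0, 4.0, len(I))
        with pytest.warns(UserWarning, match="respiration"):
            pm.TemperaturePICurve(y, I, T).fit()

    def test_f_statistic_large_for_structured_data(self, rng):
        I, T = self._design(rng)
        y = pm.temp_model(I, T, *TABLE2.values()) + rng.normal(0, 3.79, len(I))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pm.TemperaturePICurve(y, I, T).fit()
        assert fit.f_statistic > 30
        assert fit.f_pvalue < 1e-6
        assert fit.nobs == 171

    def test_summary_and_coef_table(self, rng):
        I, T = self._design(rng)
        y = pm.temp_model(I, T, *TABLE2.values()) + rng.normal(0, 2.0, len(I))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pm.TemperaturePICurve(y, I, T).fit()
        assert set(fit.coef_table().columns) == {"estimate", "se", "t", "p"}
        assert "Pmax" in fit.summary()


class TestPredictCi:
    def _fit(self, rng):
        I = rng.uniform(2, 160, 171)
        T = rng.uniform(7.5, 13.5, 171)
        y = pm.temp_model(I, T, *TABLE2.values()) + rng.normal(0, 3.79, 171)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return pm.TemperaturePICurve(y, I, T).fit()

    def test_zero_covariance_collapses_to_point(self, rng):
        fit = self._fit(rng)
        fit._cov = np.zeros((3, 3))
        pred, half = fit.predict_ci(100.0, 9.0)
        assert half == pytest.approx(0.0, abs=1e-12)

    def test_half_width_monotone_in_covariance_scale(self, rng):
        fit = self._fit(rng)
        _, h1 = fit.predict_ci(100.0, 9.0)
        fit._cov = fit._cov * 4.0
        _, h2 = fit.predict_ci(100.0, 9.0)
        assert h2 == pytest.approx(2 * h1, rel=1e-6)
        assert h2 > h1 >= 0

    def test_band_covers_truth_at_most_design_points(self, rng):
        """Delta-method 95% bands cover the noiseless truth at >= 90% of a
        grid of design points, averaged over seeded refits."""
        hits = total = 0
        for _ in range(25):
            fit = self._fit(rng)
            I = np.linspace(5, 150, 12)
            T = np.linspace(7.6, 13.4, 12)
            truth = pm.temp_model(I, T, *TABLE2.values())
            pred, half = fit.predict_ci(I, T)
            hits += int(np.sum(np.abs(pred - truth) <= half))
            total += len(I)
        assert hits / total >= 0.90


class TestBins:
    def test_default_bins_match_design(self):
        labels = {b.label: (b.t_min, b.t_max) for b in pm.DEFAULT_BINS}
        assert labels == {"low": (7.5, 8.5), "medium": (10.1, 11.1),
                          "high": (11.5, 12.6), "extreme": (13.0, 13.5)}
        assert not pm.DEFAULT_BINS[3].include_respiration

    def test_closed_left_open_right(self):
        assert pm.assign_bin(7.5).label == "low"
        assert pm.assign_bin(8.5) is None
        assert pm.assign_bin(13.49).label == "extreme"
        assert pm.assign_bin(13.5) is None
        assert pm.assign_bin(9.0) is None  # between bins -> excluded
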