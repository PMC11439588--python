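"""Scenario generator: offset profiles, ambient/PAR models, incubation traces."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kelpmetab import scenarios as sc
from kelpmetab.incubations import MesocosmGeometry, hourly_rate, to_areal


class TestOffsetProfile:
    def test_control_is_zero_everywhere(self, hourly_timeline):
        off = sc.offset_profile(sc.ScenarioSpec.for_treatment("control"),
                                hourly_timeline)
        assert (off == 0).all()

    def test_ht_reaches_and_holds_base_offset(self, hourly_timeline):
        off = sc.offset_profile(sc.ScenarioSpec.for_treatment("HT"),
                                hourly_timeline)
        assert off.max() == pytest.approx(1.8)
        # after acclimation (2 d) + ramp (3 d) the offset stays at +1.8
        assert (off.iloc[5 * 24:] == 1.8).all()
        # ~0.6 degC per day during the ramp
        ramp = off.iloc[2 * 24: 5 * 24]
        assert np.allclose(np.diff(ramp), 1.8 / 3 / 24)

    def test_1mh_plateau_inside_peak(self, hourly_timeline):
        spec = sc.ScenarioSpec.for_treatment("1MH")
        off = sc.offset_profile(spec, hourly_timeline)
        # any time inside the 13-day peak sits at +2.8
        inside = off.iloc[9 * 24: 20 * 24]
        assert (inside == 2.8).all()
        assert off.max() == pytest.approx(2.8)

    def test_2mh_run_length_structure(self, hourly_timeline):
        """Run-length encoding: exactly two 5-day maximal plateaus separated
        by a 3-day base-offset interval."""
        off = sc.offset_profile(sc.ScenarioSpec.for_treatment("2MH"),
                                hourly_timeline).to_numpy()
        peaks = sc.plateau_segments(off, 3.9)
        assert len(peaks) == 2
        assert [p[2] for p in peaks] == [5 * 24.0, 5 * 24.0]
        gap_h = peaks[1][0] - peaks[0][1] - 2 * 16  # minus the two 16-h ramps
        assert gap_h == 3 * 24

    def test_profiles_are_continuous_piecewise_linear(self, hourly_timeline):
        for tr in sc.TREATMENTS:
            spec = sc.ScenarioSpec.for_treatment(tr)
            off = sc.offset_profile(spec, hourly_timeline).to_numpy()
            max_rate = max(spec.base_offset / spec.ramp_days,
                           spec.peak_ramp_rate) / 24.0
            assert np.max(np.abs(np.diff(off))) <= max_rate + 1e-12
            assert off.max() == pytest.approx(
                spec.peak_offset if spec.n_peaks else spec.base_offset)

    def test_short_timeline_error_reports_required_length(self):
        tl = pd.date_range("2022-06-30", periods=48, freq="1h")
        with pytest.raises(ValueError, match="529 hourly samples"):
            sc.offset_profile(sc.ScenarioSpec.for_treatment("1MH"), tl)

    def test_time_above_intermediate_threshold_orders_1mh_over_2mh(
            self, hourly_timeline):
        """For any threshold between base and peak, the long moderate event
        exceeds it longer than the two short intense events."""
        off1 = sc.offset_profile(sc.ScenarioSpec.for_treatment("1MH"),
                                 hourly_timeline).to_numpy()
        off2 = sc.offset_profile(sc.ScenarioSpec.for_treatment("2MH"),
                                 hourly_timeline).to_numpy()
        for eps in (0.1, 0.5, 0.9):
            thr = 1.8 + eps
            assert (off1 > thr).sum() > (off2 > thr).sum()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="control"):
            sc.ScenarioSpec("control", base_offset=1.0)
        with pytest.raises(ValueError, match="two peaks"):
            sc.ScenarioSpec("2MH", peak_offset=3.9, peak_duration_days=5,
                            n_peaks=1)
        with pytest.raises(ValueError, match="nonnegative"):
            sc.ScenarioSpec("HT", base_offset=-1.0)


class TestAmbient:
    def test_degenerate_model_is_constant(self, hourly_timeline):
        m = sc.AmbientModel(mean_temp=9.0, seasonal_trend=0, diel_amplitude=0,
                            noise_sd=0)
        t = sc.ambient_series(m, hourly_timeline)
        assert np.allclose(t, 9.0)

    def test_fixed_seed_reproducible(self, hourly_timeline):
        m = sc.AmbientModel(seed=42)
        a = sc.ambient_series(m, hourly_timeline)
        b = sc.ambient_series(m, hourly_timeline)
        assert (a == b).all()

    def test_default_median_in_target_band(self, hourly_timeline):
        m = sc.AmbientModel()
        for seed in (0, 1, 2, 3):
            t = sc.ambient_series(m, hourly_timeline, seed=seed)
            lo, hi = m.target_band
            assert lo <= t.median() <= hi

    def test_ar1_bounds_enforced(self):
        with pytest.raises(ValueError, match="ar1"):
            sc.AmbientModel(ar1_coef=1.0)

    def test_stationary_noise_scale_independent_of_cadence(self):
        m = sc.AmbientModel(seasonal_trend=0, diel_amplitude=0, noise_sd=0.3,
                            ar1_coef=0.8)
        minute = pd.date_range("2022-06-30", periods=7 * 1440, freq="1min")
        t = sc.ambient_series(m, minute, seed=5)
        assert 0.2 < t.std() < 0.45


class TestPar:
    def test_degenerate_range_gives_exact_integrals(self, hourly_timeline):
        m = sc.ParModel(daily_integral_range=(20.0, 20.0), replicate_sd=0,
                        day_noise_sd=0)
        par = sc.par_series(m, hourly_timeline)
        daily = par.to_numpy().reshape(23, 24).sum(axis=1) / 1000.0
        assert np.allclose(daily, 20.0)

    def test_default_integrals_within_range_and_nonnegative(self, hourly_timeline):
        m = sc.ParModel()
        par = sc.par_series(m, hourly_timeline, seed=3)
        assert (par >= 0).all()
        daily = par.to_numpy().reshape(23, 24).sum(axis=1) / 1000.0
        assert daily.min() >= 14.0 - 1e-9
        assert daily.max() <= 65.0 + 1e-9

    def test_reintegration_matches_clipped_targets(self, hourly_timeline, rng):
        """Summing the hourly series over one day and converting to mol
        reproduces the day's target integral exactly."""
        m = sc.ParModel()
        targets = m.day_targets(23, rng)
        par = sc.par_series(m, hourly_timeline, seed=11, day_targets=targets)
        daily = par.to_numpy().reshape(23, 24).sum(axis=1) / 1000.0
        assert np.allclose(daily, targets)

    def test_negative_bounds_rejected(self):
        with pytest.raises(ValueError):
            sc.ParModel(daily_integral_range=(-1.0, 65.0))


class TestSimulateIncubation:
    def test_noiseless_roundtrip_recovers_truth(self):
        """OLS slope on the noiseless trace equals the ground-truth NCP after
        areal conversion, to machine precision."""
        truth = sc.TruthParams(pmax=22.0, alpha=0.015, rd=-5.0,
                               o2_noise_sd=0.0)
        geom = MesocosmGeometry(1000.0, sc.DEFAULT_AREA_M2)
        trace = sc.simulate_incubation(truth, 9.0, [800.0, 1500.0, 3000.0],
                                       volume_l=geom.volume_l,
                                       area_m2=geom.footprint_area_m2)
        for h in range(3):
            seg = trace.iloc[h * 60:(h + 1) * 60]
            slope, se, r2, n = hourly_rate(seg)
            want = float(truth.ncp([800.0, 1500.0, 3000.0][h], 9.0))
            got = to_areal(slope, geom)
            assert got == pytest.approx(want, rel=1e-9)
            assert se == pytest.approx(0.0, abs=1e-9)

    def test_dark_trace_with_negative_rd_decreases(self):
        truth = sc.TruthParams(rd=-5.0, o2_noise_sd=0.0)
        trace = sc.simulate_incubation(truth, 9.0, 0.0)
        assert (np.diff(trace) < 0).all()

    def test_noisy_recovery_is_unbiased(self, rng):
        """Across 200 noisy incubations the mean recovered slope sits within
        2 standard errors of the ground truth."""
        truth = sc.TruthParams(pmax=22.0, alpha=0.015, rd=-5.0,
                               o2_noise_sd=1.0)
        geom = MesocosmGeometry(1000.0, sc.DEFAULT_AREA_M2)
        want = float(truth.ncp(1500.0, 9.0))
        got = []
        for k in range(200):
            trace = sc.simulate_incubation(truth, 9.0, 1500.0, duration_h=1,
                                           seed=int(rng.integers(2**31)))
            slope, *_ = hourly_rate(trace)
            got.append(to_areal(slope, geom))
        got = np.asarray(got)
        sem = got.std(ddof=1) / np.sqrt(len(got))
        assert abs(got.mean() - want) < 2 * sem

    def test_seed_reproducibility_and_validation(self):
        truth = sc.TruthParams()
        a = sc.simulate_incubation(truth, 9.0, 1000.0, seed=7)
        b = sc.simulate_incubation(truth, 9.0, 1000.0, seed=7)
        assert (a == b).all()
        with pytest.raises(ValueError, match="volume"):
            sc.simulate_incubation(truth, 9.0, 1000.0, volume_l=-1)
        with pytest.raises(ValueError, match="dt_min"):
            sc.simulate_incubation(truth, 9.0, 1000.0, dt_min=7)


class TestGenerateExperiment:
    def test_twelve_mesocosms_23_days(self, experiment):
        assert len(experiment.mesocosms()) == 12
        for mid in experiment.mesocosms():
            o2 = experiment.get(mid, "O2")
            span = o2.timestamps[-1] - o2.timestamps[0]
            assert span == pd.Timedelta(days=23) - pd.Timedelta(minutes=1)

    def test_replicate_par_differs_but_daily_sd_bounded(self, experiment):
        """Replicates see different irradiance, but the mean across-replicate
        SD of daily integrals stays within the observed range (<= 2.99)."""
        daily = []
        for rep in (1, 2, 3):
            par = experiment.get(f"control-{rep}", "PAR").values
            daily.append(par.reshape(23, 144).reshape(23, 24, 6).mean(-1).sum(-1)
                         / 1000.0)
        daily = np.asarray(daily)
        assert not np.allclose(daily[0], daily[1])
        # skip the two dark-incubation days (logger under the blackout cover)
        keep = [d for d in range(23) if d not in (1, 10)]
        mean_sd = daily[:, keep].std(axis=0, ddof=1).mean()
        assert 0.0 < mean_sd <= 2.99

    def test_master_seed_determinism_on_disk(self, tmp_path):
        cfg = sc.ExperimentConfig(days=23)
        sc.generate_experiment(cfg, seed=99, out_dir=tmp_path / "a")
        sc.generate_experiment(cfg, seed=99, out_dir=tmp_path / "b")
        for name in ("schedule.csv", "manifest.yaml", "2MH-3_O2.csv",
                     "control-1_PAR.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_schedule_counts_match_design(self, experiment):
        sched = experiment.schedule
        light = sched[sched["mode"] == "light"]
        dark = sched[sched["mode"] == "dark"]
        per_treatment = light.groupby("treatment")["mesocosm_id"].count() / 3
        assert per_treatment.to_dict() == {"1MH": 6, "2MH": 8, "HT": 4,
                                           "control": 4}
        assert (dark.groupby("mesocosm_id").size() == 2).all()

    def test_structural_invariants_across_seeds(self):
        """Changing only the seed preserves plateau structure and PAR bounds."""
        tl = pd.date_range("2022-06-30", periods=23 * 24, freq="1h")
        for seed in (5, 6):
            cfg = sc.ExperimentConfig(seed=seed)
            exp = sc.generate_experiment(cfg)
            off2 = sc.offset_profile(sc.ScenarioSpec.for_treatment("2MH"), tl)
            assert len(sc.plateau_segments(off2.to_numpy(), 3.9)) == 2
            par = exp.get("1MH-2", "PAR").values
            assert par.min() >= 0.0
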