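import numpy as np
import pytest
import statsmodels.api as sm

from sacspike.interaction import (InteractionError, amplitude_timecourse,
                                  eccentricity_slope_profile,
                                  estimate_efferent_lag, filter_levels,
                                  fit_amplitude_model, fit_interaction_model,
                                  influence_window_halfwidth,
                                  intra_saccadic_count, moving_average,
                                  select_movements, sort_and_test_timing,
                                  spike_timecourse_by_amplitude)
from sacspike.kinematics import Saccade
from sacspike.spikes import SpikeTrain


def sacc(trial, onset, amplitude=0.15, direction=0.0):
    return Saccade(onset_ms=onset, peak_vel_ms=onset + 7, offset_ms=onset + 15,
                   amplitude=amplitude, peak_velocity=15.0, direction=direction,
                   trial_id=trial)


class TestIntraSaccadicCount:
    def test_spikes_inside_window_counted(self):
        s = sacc("t", 300.0)
        tr = SpikeTrain("t", "n", np.array([301.0, 310.0, 319.0]))
        assert intra_saccadic_count(s, tr) == 3

    def test_spikes_after_window_ignored(self):
        s = sacc("t", 300.0)
        tr = SpikeTrain("t", "n", np.array([325.0]))
        assert intra_saccadic_count(s, tr) == 0

    def test_matches_linear_scan_oracle(self, rng):
        for _ in range(30):
            s = sacc("t", float(rng.uniform(100, 500)))
            times = np.sort(rng.uniform(0, 700, 60))
            tr = SpikeTrain("t", "n", times)
            brute = sum(1 for t in times if s.onset_ms <= t < s.onset_ms + 20.0)
            assert intra_saccadic_count(s, tr) == brute


class TestSelectMovements:
    STIM = {"a": 1000.0, "b": 1000.0, "c": 1000.0}

    def test_post_stimulus_window(self):
        out = select_movements([sacc("a", 1100.0)], self.STIM, "post_stimulus")
        assert len(out) == 1

    def test_sustained_window(self):
        out = select_movements([sacc("a", 1600.0)], self.STIM, "sustained")
        assert len(out) == 1
        assert select_movements([sacc("a", 1500.0)], self.STIM, "sustained") == []

    def test_baseline_window(self):
        out = select_movements([sacc("a", 300.0)], self.STIM, "baseline")
        assert len(out) == 1

    def test_post_stimulus_keeps_first_per_trial_only(self):
        out = select_movements([sacc("a", 1150.0), sacc("a", 1050.0)],
                               self.STIM, "post_stimulus")
        assert [s.onset_ms for s in out] == [1050.0]

    def test_unknown_mode_rejected(self):
        with pytest.raises(InteractionError):
            select_movements([], self.STIM, "whenever")


class TestAmplitudeModel:
    def test_exact_linear_data_interpolated(self):
        counts = np.repeat([0, 1, 2, 3], 20)
        amps = 0.1 + 0.05 * counts
        f = fit_amplitude_model(counts, amps)
        assert f.beta0 == pytest.approx(0.1, abs=1e-12)
        assert f.beta1 == pytest.approx(0.05, abs=1e-12)

    def test_constant_amplitudes_give_zero_slope_and_f(self):
        counts = np.repeat([0, 1, 2], 20)
        f = fit_amplitude_model(counts, np.full(60, 0.15))
        assert f.beta1 == pytest.approx(0.0, abs=1e-12)
        assert f.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_ols(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 4, 200)
            amps = 0.12 + 0.05 * counts + rng.normal(0, 0.04, 200)
            f = fit_amplitude_model(counts, amps)
            X = sm.add_constant(counts.astype(float))
            ref = sm.OLS(amps, X).fit()
            assert f.beta0 == pytest.approx(ref.params[0], abs=1e-10)
            assert f.beta1 == pytest.approx(ref.params[1], abs=1e-10)
            assert f.se0 == pytest.approx(ref.bse[0], abs=1e-10)
            assert f.se1 == pytest.approx(ref.bse[1], abs=1e-10)
            assert f.p1 == pytest.approx(ref.pvalues[1], abs=1e-10)
            assert f.F == pytest.approx(ref.fvalue, rel=1e-10)
            robust = ref.get_robustcov_results(cov_type="HC1")
            assert f.se1_robust == pytest.approx(robust.bse[1], abs=1e-10)

    def test_f_equals_squared_slope_t(self, rng):
        counts = rng.integers(0, 5, 300)
        amps = 0.1 + 0.03 * counts + rng.normal(0, 0.05, 300)
        f = fit_amplitude_model(counts, amps)
        assert f.F == pytest.approx(f.t1 ** 2, rel=1e-9)

    def test_sparse_levels_dropped_before_fitting(self):
        counts = np.concatenate([np.zeros(30), np.ones(30), np.full(3, 2)])
        amps = 0.1 + 0.05 * counts
        f = fit_amplitude_model(counts.astype(int), amps)
        assert f.levels_used == [0, 1]
        assert f.n_obs == 60

    def test_single_level_after_filtering_rejected(self):
        with pytest.raises(InteractionError):
            fit_amplitude_model(np.zeros(40, int), np.full(40, 0.1))


class TestFilterLevels:
    def test_reported_level_counts_all_retained(self):
        counts = {0: 1772, 1: 383, 2: 237, 3: 145, 4: 113, 5: 78}
        assert filter_levels(counts) == [0, 1, 2, 3, 4, 5]

    def test_sparse_level_dropped(self):
        assert filter_levels({0: 30, 1: 14}) == [0]

    def test_levels_above_five_dropped_regardless_of_count(self):
        counts = {i: 50 for i in range(7)}
        assert filter_levels(counts) == [0, 1, 2, 3, 4, 5]


class TestInteractionModel:
    def test_noiseless_design_recovers_interaction_exactly(self, rng):
        n = rng.integers(0, 5, 400)
        ecc = rng.choice([1.0, 3.0, 5.0, 8.0], 400)
        amp = 0.12 + (0.09 - 0.008 * ecc) * n
        f = fit_interaction_model(n, ecc, amp)
        assert f.interaction == pytest.approx(-0.008, abs=1e-12)
        assert f.beta[1] == pytest.approx(0.09, abs=1e-12)

    def test_matches_statsmodels(self, rng):
        n = rng.integers(0, 5, 300).astype(float)
        ecc = rng.uniform(1, 9, 300)
        amp = 0.1 + 0.05 * n + 0.001 * ecc - 0.004 * n * ecc + rng.normal(0, 0.03, 300)
        f = fit_interaction_model(n.astype(int), ecc, amp)
        X = sm.add_constant(np.column_stack([n, ecc, n * ecc]))
        ref = sm.OLS(amp, X).fit()
        assert np.allclose(f.beta, ref.params, atol=1e-10)
        assert np.allclose(f.se, ref.bse, atol=1e-10)

    def test_constant_eccentricity_is_rank_deficient(self, rng):
        n = rng.integers(0, 5, 100)
        with pytest.raises(InteractionError):
            fit_interaction_model(n, np.full(100, 3.0), 0.1 + 0.05 * n)


class TestEccentricityProfile:
    def test_window_membership_defines_centers(self, rng):
        # all neurons at 3 deg: only the 2/3/4-deg windows contain them
        eccs = {f"n{i}": 3.0 for i in range(4)}
        nid = rng.choice(list(eccs), 400)
        counts = rng.integers(0, 4, 400)
        amps = 0.12 + 0.05 * counts + rng.normal(0, 0.02, 400)
        prof = eccentricity_slope_profile(eccs, nid, counts, amps)
        defined = set(prof.centers[~np.isnan(prof.slopes)])
        assert defined == {2.0, 3.0, 4.0}

    def test_gain_declining_with_eccentricity_gives_declining_slopes(self, rng):
        eccs = {f"n{k}": float(k) for k in range(1, 9)}
        nid = rng.choice(list(eccs), 6000)
        ecc_arr = np.array([eccs[i] for i in nid])
        counts = rng.integers(0, 5, 6000)
        amps = 0.12 + (0.1 - 0.01 * ecc_arr) * counts + rng.normal(0, 0.02, 6000)
        prof = eccentricity_slope_profile(eccs, nid, counts, amps)
        ok = ~np.isnan(prof.slopes)
        assert np.all(np.diff(prof.slopes[ok]) < 0)

    def test_empty_window_is_undefined(self, rng):
        eccs = {"n0": 6.0}
        nid = np.array(["n0"] * 100)
        counts = rng.integers(0, 3, 100)
        amps = 0.1 + 0.05 * counts + rng.normal(0, 0.01, 100)
        prof = eccentricity_slope_profile(eccs, nid, counts, amps)
        at1 = np.flatnonzero(prof.centers == 1.0)[0]
        assert np.isnan(prof.slopes[at1])
        assert prof.n_neurons[at1] == 0


class TestAmplitudeTimecourse:
    def test_flat_amplitudes_give_flat_curve(self, rng):
        t = rng.uniform(-100, 150, 500)
        c, mean, sem, n = amplitude_timecourse(t, np.full(500, 0.15))
        assert np.allclose(mean[n > 0], 0.15)

    def test_elevation_confined_to_overlapping_windows(self, rng):
        t = np.concatenate([rng.uniform(-100, 50, 400), rng.uniform(50, 100, 400)])
        a = np.concatenate([np.full(400, 0.12), np.full(400, 0.30)])
        centers, mean, sem, n = amplitude_timecourse(t, a)
        # windows that cannot touch (50, 100): center + 25 <= 50
        untouched = centers <= 25.0 - 1e-9
        assert np.allclose(mean[untouched & (n > 0)], 0.12)
        inside = (centers >= 75) & (centers <= 75)
        assert np.all(mean[inside] > 0.2)

    def test_single_movement_defined_only_near_it(self):
        centers, mean, sem, n = amplitude_timecourse([0.0], [0.2])
        has = ~np.isnan(mean)
        assert np.allclose(centers[has], centers[np.abs(centers) <= 25])
        assert np.allclose(mean[has], 0.2)

    def test_moving_average_display_helper(self):
        out = moving_average(np.arange(10.0), width=5, step=1)
        assert np.allclose(out, np.arange(2.0, 8.0))


class TestTimingSort:
    def _step_data(self, rng, n_bins_elevated=(3, 10), amp_hi=0.30):
        # sorted key: bins 0-2 baseline, 3-9 elevated, 10-14 baseline again
        n = 30 * 15
        key = np.arange(n, dtype=float)
        amp = np.full(n, 0.12) + rng.normal(0, 0.01, n)
        lo, hi = n_bins_elevated
        amp[30 * lo:30 * hi] = amp_hi + rng.normal(0, 0.01, 30 * (hi - lo))
        return key, amp

    def test_step_onset_and_offset_bins_found(self, rng):
        key, amp = self._step_data(rng)
        res = sort_and_test_timing(key, amp)
        assert res.start_bin == 3
        assert res.end_bin == 10

    def test_null_data_rarely_triggers(self, rng):
        hits = 0
        for _ in range(100):
            key = np.arange(300.0)
            amp = rng.normal(0.15, 0.02, 300)
            res = sort_and_test_timing(key, amp)
            hits += res.start_bin is not None
        assert hits <= 5  # Bonferroni keeps the false-start rate below alpha

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(InteractionError):
            sort_and_test_timing(np.arange(59.0), rng.normal(0.1, 0.01, 59))

    def test_end_to_end_on_generated_sessions(self):
        # movements whose onsets fall just after the visual-burst peak carry
        # extra spikes and are enlarged; sorting by burst-minus-onset time
        # must localize that elevation around zero
        from sacspike.simulate import fixture_config, simulate_session
        from sacspike.pipeline import amplitude_dataset

        cfg = fixture_config("step_timing", seed=1, n_trials=3000)
        bundle, _ = simulate_session(cfg)
        data = amplitude_dataset(bundle)
        tow = data[data["toward"]]
        stim = {t.trial_id: t.stimulus_onset_ms for t in bundle.trials}
        cond = {t.trial_id: t.condition_value for t in bundle.trials}
        peak = {tid: stim[tid] + cfg.burst_latency[cond[tid]] + cfg.burst_tau
                for tid in stim}
        onset_abs = tow["onset_rel_stim_ms"].to_numpy() + np.array(
            [stim[tid] for tid in tow["trial_id"]])
        key = np.array([peak[tid] for tid in tow["trial_id"]]) - onset_abs
        res = sort_and_test_timing(key, tow["amplitude"].to_numpy())
        assert res.start_bin is not None
        assert -50.0 <= res.bin_times[res.start_bin] <= 20.0
        assert res.end_bin is not None
        assert res.bin_times[res.end_bin] > res.bin_times[res.start_bin]


class TestSpikeTimecourseByAmplitude:
    def test_no_spikes_gives_zeros(self):
        s = [sacc("t", 500.0, amplitude=0.25)]
        tr = [SpikeTrain("t", "n", np.array([]))]
        tc = spike_timecourse_by_amplitude(s, tr)
        assert np.all(tc.mean_count == 0.0)

    def test_homogeneous_poisson_flat_at_nominal(self, rng):
        rate = 40.0
        saccades, trains = [], []
        for i in range(800):
            saccades.append(sacc(f"t{i}", 500.0, amplitude=float(rng.uniform(0.11, 0.79))))
            n = rng.poisson(rate)  # 1000 ms of spiking around the movement
            trains.append(SpikeTrain(f"t{i}", "n", np.sort(rng.uniform(0, 1000, n))))
        tc = spike_timecourse_by_amplitude(saccades, trains)
        pooled = np.vstack([c for c in tc.counts if c.size]).mean(axis=0)
        # per-bin Monte-Carlo sd is sqrt(0.2/800) ~ 0.016; allow ~4 sd
        assert np.allclose(pooled, 0.005 * rate, atol=0.06)

    def test_elevation_confined_to_loaded_bins(self, rng):
        saccades, trains = [], []
        for i in range(400):
            big = i % 2 == 0
            amp = 0.55 if big else 0.15
            times = [500.0 + dt for dt in rng.uniform(-10, 10, 8)] if big else []
            saccades.append(sacc(f"t{i}", 500.0, amplitude=amp))
            trains.append(SpikeTrain(f"t{i}", "n", np.sort(times)))
        tc = spike_timecourse_by_amplitude(saccades, trains)
        big_bin = np.flatnonzero(tc.n_movements)[-1]
        centers = (tc.time_edges[:-1] + tc.time_edges[1:]) / 2
        inside = np.abs(centers) <= 10
        assert tc.mean_count[big_bin][inside].sum() > 0
        assert tc.mean_count[big_bin][~inside].sum() == 0


class TestEfferentLag:
    def _curve(self, shift=0.0):
        t = np.arange(-100.0, 151.0)
        return t, np.exp(-0.5 * ((t - 50.0 - shift) / 20) ** 2)

    def test_identical_curves_have_zero_lag(self):
        t, y = self._curve()
        assert estimate_efferent_lag(t, y, t, y) == 0.0

    def test_shifted_curve_recovers_shift(self):
        t, y = self._curve()
        _, yb = self._curve(shift=20.0)
        assert estimate_efferent_lag(t, yb, t, y) == pytest.approx(20.0, abs=1.0)

    def test_noisy_shift_recovered_within_tolerance(self, rng):
        t, y = self._curve()
        for _ in range(10):
            _, yb = self._curve(shift=20.0)
            yb = yb + rng.normal(0, 0.02, yb.size)
            lag = estimate_efferent_lag(t, yb, t, y)
            assert abs(lag - 20.0) <= 5.0

    def test_non_overlapping_grids_rejected(self):
        t, y = self._curve()
        with pytest.raises(InteractionError):
            estimate_efferent_lag(t, y, t + 1000.0, y)
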