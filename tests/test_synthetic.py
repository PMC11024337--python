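import numpy as np
import pytest
import scipy.signal

from thetatrain.behavior import dprime, learning_slope, sdt_counts
from thetatrain.synthetic import (
    SIMPLE_CUE,
    CohortEffects,
    SimulationConfig,
    SubjectProfile,
    build_protocol,
    schedule_tms,
    simulate_cohort,
    simulate_epochs,
    simulate_responses,
)


class TestBuildProtocol:
    def test_default_session_counts(self):
        proto = build_protocol(3, 42, 14, seed=0)
        assert proto.n_trials == 126
        assert proto.n_manipulation == 84
        assert proto.n_simple == 42

    def test_single_simple_trial(self):
        proto = build_protocol(1, 1, 1, seed=0)
        assert proto.n_trials == 1
        assert proto.trials[0].trial_type == "simple"
        assert proto.trials[0].cue == SIMPLE_CUE

    def test_deterministic_given_seed(self):
        a = build_protocol(2, 4, 2, seed=7)
        b = build_protocol(2, 4, 2, seed=7)
        assert a.trials == b.trials

    def test_seed_changes_order(self):
        a = build_protocol(2, 42, 14, seed=1)
        b = build_protocol(2, 42, 14, seed=2)
        assert a.trials != b.trials

    def test_cue_invariants(self):
        proto = build_protocol(2, 42, 14, seed=3)
        for spec in proto.trials:
            if spec.trial_type == "simple":
                assert spec.cue == SIMPLE_CUE
            else:
                assert spec.cue != SIMPLE_CUE
                assert sorted(spec.cue) == ["1", "2", "3"]

    def test_timing_invariants(self):
        proto = build_protocol(1, 2, 1, seed=0)
        assert proto.cue_onset_ms == 5000.0
        assert proto.probe_onset_ms == 10000.0
        assert proto.trial_duration_ms == 15000.0

    @pytest.mark.parametrize("runs,tpr,ns", [(0, 42, 14), (1, 0, 0), (-1, 5, 2)])
    def test_rejects_nonpositive_counts(self, runs, tpr, ns):
        with pytest.raises(ValueError):
            build_protocol(runs, tpr, ns)

    def test_rejects_too_many_simple(self):
        with pytest.raises(ValueError):
            build_protocol(1, 4, 5)


class TestScheduleTms:
    def test_block_of_420_pulses(self):
        proto = build_protocol(1, 42, 14, seed=0)
        sched = schedule_tms(proto, 5.0, 10)
        assert sched.total_pulses == 420
        np.testing.assert_allclose(
            sched.train_onsets_ms, 5000.0 + 200.0 * np.arange(10)
        )
        assert sched.train_onsets_ms[-1] == 6800.0

    def test_single_pulse(self):
        proto = build_protocol(1, 3, 1, seed=0)
        sched = schedule_tms(proto, 5.0, 1)
        assert sched.total_pulses == 3
        assert np.all(sched.pulse_onsets_ms == 5000.0)

    def test_inter_pulse_interval_at_10hz(self):
        proto = build_protocol(1, 3, 1, seed=0)
        sched = schedule_tms(proto, 10.0, 4)
        assert sched.total_pulses == 12
        np.testing.assert_allclose(np.diff(sched.train_onsets_ms), 100.0)

    def test_overrun_warns_but_succeeds(self):
        proto = build_protocol(1, 2, 1, seed=0)
        with pytest.warns(UserWarning, match="probe"):
            sched = schedule_tms(proto, 1.0, 6)  # last pulse at 10000 ms
        assert sched.total_pulses == 12

    @pytest.mark.parametrize("freq,n", [(0, 10), (-5, 10), (5, 0)])
    def test_invalid_args(self, freq, n):
        proto = build_protocol(1, 2, 1, seed=0)
        with pytest.raises(ValueError):
            schedule_tms(proto, freq, n)


class TestSimulateCohort:
    def test_sizes_and_balance(self):
        profiles = simulate_cohort(7, seed=5)
        assert len(profiles) == 14
        rh = [p for p in profiles if p.group == "rhTMS"]
        sh = [p for p in profiles if p.group == "sham"]
        assert len(rh) == len(sh) == 7
        diff = (np.mean([p.baseline_dprime_manip for p in rh])
                - np.mean([p.baseline_dprime_manip for p in sh]))
        assert abs(diff) <= 0.25

    def test_null_effects_have_no_group_gains(self):
        profiles = simulate_cohort(5, CohortEffects.null(), seed=1)
        for p in profiles:
            assert p.entrainment_gain == 0.0
            assert p.lasting_gain == 0.0

    def test_sham_entrainment_always_zero(self):
        for seed in range(5):
            for p in simulate_cohort(4, seed=seed):
                if p.group == "sham":
                    assert p.entrainment_gain == 0.0

    def test_deterministic(self):
        a = simulate_cohort(3, seed=9)
        b = simulate_cohort(3, seed=9)
        assert a == b

    def test_slope_difference_monte_carlo(self):
        # mean fitted slope difference over many cohorts ~ programmed 0.2
        effects = CohortEffects(slope_diff=0.2)
        diffs = []
        for seed in range(120):
            profiles = simulate_cohort(10, effects, seed=seed)
            rh = np.mean([p.slope_manip for p in profiles
                          if p.group == "rhTMS"])
            sh = np.mean([p.slope_manip for p in profiles
                          if p.group == "sham"])
            diffs.append(rh - sh)
        assert np.mean(diffs) == pytest.approx(0.2, abs=0.01)

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            simulate_cohort(0)

    def test_impossible_balance_reported(self):
        with pytest.raises(RuntimeError, match="balance"):
            simulate_cohort(3, balance_tol=0.0, max_retries=3, seed=0)


class TestSimulateResponses:
    def _estimate_dprime(self, profile, n_trials, session=1, seed=0):
        proto = build_protocol(1, n_trials, 0, seed=1)
        rng = np.random.default_rng(seed)
        table = simulate_responses(profile, proto, session, rng)
        return dprime(*sdt_counts(table)).dprime

    def test_chance_performer(self):
        p = SubjectProfile("X", "sham", 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, seed=0)
        proto = build_protocol(1, 4000, 0, seed=1)
        table = simulate_responses(p, proto, 1, np.random.default_rng(0))
        assert table["correct"].mean() == pytest.approx(0.5, abs=0.03)

    def test_large_sample_dprime_recovery(self):
        p = SubjectProfile("X", "sham", 2.5, 2.5, 0.0, 0.0, 0.0, 0.0, seed=0)
        est = self._estimate_dprime(p, 10_000)
        assert est == pytest.approx(2.5, abs=0.1)

    def test_slope_recovery_by_regression(self):
        p = SubjectProfile("X", "sham", 1.0, 1.0, 0.2, 0.0, 0.0, 0.0, seed=0)
        by_session = {
            s: self._estimate_dprime(p, 10_000, session=s, seed=s)
            for s in range(2, 7)
        }
        fit = learning_slope(by_session)
        assert fit.slope == pytest.approx(0.2, abs=0.02)

    def test_session_bounds(self, profile, small_protocol):
        with pytest.raises(ValueError):
            simulate_responses(profile, small_protocol, 0,
                               np.random.default_rng(0))

    def test_correctness_coding(self, profile, small_protocol):
        table = simulate_responses(profile, small_protocol, 1,
                                   np.random.default_rng(3))
        manual = (table["response"] == "mismatch") == ~table["is_match"]
        assert (table["correct"] == manual).all()


class TestSimulateEpochs:
    def test_silence(self, montage62, small_protocol):
        cfg = SimulationConfig(sampling_rate=500.0, noise_amplitude_uv=0.0,
                               seed=0)
        quiet = SubjectProfile("X", "sham", 1.0, 1.0, 0.0, 0.0, 0.0, 0.0,
                               seed=0)
        ep = simulate_epochs(quiet, small_protocol, None, montage62, cfg)
        assert np.all(ep.data == 0.0)

    def test_epoch_geometry(self, profile, small_protocol, montage62,
                            sim_config):
        ep = simulate_epochs(profile, small_protocol, None, montage62,
                             sim_config)
        assert ep.times[0] == -1000.0
        assert ep.times[-1] < 12000.0
        assert ep.data.shape == (6, 62, 6500)
        assert list(ep.metadata["trial_type"]) == [
            s.trial_type for s in small_protocol.trials
        ]

    def test_theta_power_in_window_welch_oracle(self, profile, montage62):
        cfg = SimulationConfig(sampling_rate=500.0, seed=3)
        proto = build_protocol(1, 4, 0, seed=2)  # all manipulation
        ep = simulate_epochs(profile, proto, None, montage62, cfg)
        ch = montage62.index("Pz")
        fs = ep.sampling_rate

        def band_power(x):
            f, p = scipy.signal.welch(x, fs=fs, nperseg=1024)
            return p[(f >= 4) & (f <= 8)].sum()

        win = ep.time_mask((5000.0, 10000.0))
        base = ep.time_mask((-1000.0, 4000.0))
        p_win = np.mean([band_power(ep.data[t, ch, win]) for t in range(4)])
        p_base = np.mean([band_power(ep.data[t, ch, base]) for t in range(4)])
        assert p_win > 2.0 * p_base

    def test_theta_power_scales_with_gain(self, montage62):
        proto = build_protocol(1, 4, 0, seed=2)
        powers = []
        for gain in (2.0, 6.0, 12.0):
            prof = SubjectProfile("X", "sham", 1.0, 1.0, 0.0, 0.0, gain, 0.0,
                                  seed=5)
            cfg = SimulationConfig(sampling_rate=500.0, seed=5)
            ep = simulate_epochs(prof, proto, None, montage62, cfg)
            ch = montage62.index("Pz")
            win = ep.time_mask((5000.0, 10000.0))
            f, p = scipy.signal.welch(ep.data[:, ch, win], fs=500.0,
                                      nperseg=1024, axis=-1)
            powers.append(p[:, (f >= 4) & (f <= 8)].sum(axis=-1).mean())
        assert powers[0] < powers[1] < powers[2]

    def test_artifact_amplitude(self, profile, montage62):
        cfg = SimulationConfig(sampling_rate=500.0, tms_amplitude_uv=2000.0,
                               seed=1)
        proto = build_protocol(1, 2, 0, seed=1)
        from thetatrain.synthetic import schedule_tms
        sched = schedule_tms(proto)
        ep = simulate_epochs(profile, proto, sched, montage62, cfg)
        background_sd = 10.0
        for p_ms in sched.train_onsets_ms:
            idx = int(round((p_ms - ep.times[0]) * 500.0 / 1000.0))
            peak = np.abs(ep.data[0, :, idx:idx + 3]).max()
            assert peak > 10 * background_sd

    def test_entrainment_gain_applied_only_with_schedule(
        self, profile, montage62
    ):
        proto = build_protocol(1, 2, 0, seed=1)
        sched = schedule_tms(proto)
        cfg = SimulationConfig(sampling_rate=500.0, tms_amplitude_uv=0.0,
                               seed=7)
        ep_off = simulate_epochs(profile, proto, None, montage62, cfg)
        ep_on = simulate_epochs(profile, proto, sched, montage62, cfg)
        ch = montage62.index("Pz")
        win = ep_on.time_mask((5000.0, 10000.0))
        var_on = ep_on.data[:, ch, win].var()
        var_off = ep_off.data[:, ch, win].var()
        assert var_on > var_off  # extra 2 uV of theta amplitude

    def test_byte_identical_with_fixed_seed(self, profile, small_protocol,
                                            montage62, sim_config):
        a = simulate_epochs(profile, small_protocol, None, montage62,
                            sim_config)
        b = simulate_epochs(profile, small_protocol, None, montage62,
                            sim_config)
        assert np.array_equal(a.data, b.data)

    def test_channel_count_mismatch_rejected(self, profile, small_protocol,
                                             montage62):
        cfg = SimulationConfig(n_channels=10, sampling_rate=500.0)
        with pytest.raises(ValueError):
            simulate_epochs(profile, small_protocol, None, montage62, cfg)


class TestProfileInvariants:
    def test_sham_cannot_have_gains(self):
        with pytest.raises(ValueError):
            SubjectProfile("X", "sham", 1.0, 1.0, 0.0, 0.0, 1.0, 0.5, seed=0)

    def test_negative_theta_gain_rejected(self):
        with pytest.raises(ValueError):
            SubjectProfile("X", "sham", 1.0, 1.0, 0.0, 0.0, -1.0, 0.0, seed=0)

    def test_dprime_floor(self):
        p = SubjectProfile("X", "sham", 0.5, 1.0, -0.4, 0.0, 0.0, 0.0, seed=0)
        assert p.dprime(7, "manipulation") == 0.0
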