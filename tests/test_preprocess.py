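import numpy as np
import pandas as pd
import pytest
import scipy.signal

from thetatrain.io_brainvision import ContinuousRecording, EpochedRecording, Event
from thetatrain.preprocess import (
    PulseEventList,
    bandpass_filter,
    detect_tms_pulses,
    reject_amplitude,
    replace_tms_artifacts,
    rereference_average,
    resample,
    run_preprocessing,
)
from thetatrain.synthetic import pink_noise


def _noise_recording(n_ch=4, n=10000, fs=1000.0, seed=0, amplitude=10.0):
    rng = np.random.default_rng(seed)
    x = pink_noise(rng, (n_ch, n), fs, 1.0, amplitude)
    return ContinuousRecording(x, fs, [f"ch{i}" for i in range(n_ch)])


def band_power(x, fs, lo=4.0, hi=8.0):
    f, p = scipy.signal.welch(x, fs=fs, nperseg=min(1024, x.shape[-1]))
    return p[..., (f >= lo) & (f <= hi)].sum(axis=-1)


class TestDetect:
    def test_pure_noise_no_pulses(self):
        rec = _noise_recording()
        pulses = detect_tms_pulses(rec, threshold_sd=8.0)
        assert len(pulses) == 0

    def test_planted_transient_recovery(self):
        rec = _noise_recording(seed=1)
        where = np.arange(1000, 10000, 900)[:10]
        for s in where:
            rec.samples[:, s] += 2000.0
        pulses = detect_tms_pulses(rec, threshold_sd=8.0)
        assert len(pulses) == 10
        np.testing.assert_array_equal(pulses.onsets, where)

    def test_nearby_transients_merge(self):
        rec = _noise_recording(seed=2)
        rec.samples[:, 5000] += 1500.0
        rec.samples[:, 5005] += 2000.0  # 5 ms later, inside the 20 ms merge
        pulses = detect_tms_pulses(rec, threshold_sd=8.0)
        assert len(pulses) == 1
        assert pulses.onsets[0] == 5005  # peak of the merged cluster

    def test_scheduled_detection(self):
        from thetatrain.synthetic import StimSchedule
        rec = _noise_recording(n=30000, seed=3)
        rec.events = [Event("Stimulus", 2000, "S1")]
        train = 5000.0 + 200.0 * np.arange(10)
        for p in train:
            rec.samples[:, 2000 + int(p)] += 2000.0
        sched = StimSchedule(np.tile(train, (1, 1)), 5.0, 10)
        pulses = detect_tms_pulses(rec, schedule=sched)
        assert len(pulses) == 10
        assert pulses.method == "scheduled"
        np.testing.assert_array_equal(
            pulses.onsets, 2000 + train.astype(int))

    def test_monotonic_invariant(self):
        with pytest.raises(ValueError):
            PulseEventList(np.array([5, 5, 4]), "x", 1.0)


class TestReplace:
    def test_empty_pulse_list_identity(self):
        rec = _noise_recording()
        out = replace_tms_artifacts(rec, PulseEventList(np.empty(0), "t", 8.0))
        assert np.array_equal(out.samples, rec.samples)

    def test_degenerate_constant_reference(self):
        rec = ContinuousRecording(np.full((2, 1000), 7.5), 1000.0, ["a", "b"])
        pulses = PulseEventList(np.array([500]), "t", 8.0)
        out = replace_tms_artifacts(rec, pulses,
                                    rng=np.random.default_rng(0))
        np.testing.assert_allclose(out.samples[:, 490:521], 7.5)

    def test_only_spans_change(self):
        rec = _noise_recording(seed=4)
        pulses = PulseEventList(np.array([3000, 5000]), "t", 8.0)
        out = replace_tms_artifacts(rec, pulses,
                                    rng=np.random.default_rng(1))
        mask = np.ones(rec.n_samples, dtype=bool)
        for p in (3000, 5000):
            mask[p - 10:p + 21] = False
        assert np.array_equal(out.samples[:, mask], rec.samples[:, mask])
        assert not np.array_equal(out.samples[:, ~mask],
                                  rec.samples[:, ~mask])

    def test_replacement_matches_reference_stats(self):
        # across many pulses the replaced samples converge to the reference
        # mean/SD within 4 SE
        rec = ContinuousRecording(
            np.random.default_rng(5).normal(2.0, 3.0, (1, 200000)),
            1000.0, ["a"],
        )
        onsets = np.arange(1000, 199000, 400)
        pulses = PulseEventList(onsets, "t", 8.0)
        out = replace_tms_artifacts(rec, pulses,
                                    rng=np.random.default_rng(6))
        spans = np.concatenate([
            out.samples[0, p - 10:p + 21] for p in onsets
        ])
        n = spans.size
        se_mean = 3.0 / np.sqrt(n)
        assert abs(spans.mean() - 2.0) < 4 * se_mean
        assert abs(spans.std() - 3.0) < 0.1

    def test_overlapping_reference_window_shifts(self, caplog):
        rec = _noise_recording(seed=7)
        # second pulse 30 ms after the first: its [-35,-15) window overlaps
        # the first pulse's replaced span
        pulses = PulseEventList(np.array([5000, 5030]), "t", 8.0)
        with caplog.at_level("INFO"):
            out = replace_tms_artifacts(rec, pulses,
                                        rng=np.random.default_rng(2))
        assert "shifted" in caplog.text
        assert out.samples.shape == rec.samples.shape

    def test_artifact_power_restoration(self):
        # planted artifact inflates theta power; replacement restores it
        fs = 1000.0
        rng = np.random.default_rng(8)
        n = 15000
        t = np.arange(n) / fs
        theta = 5.0 * np.sin(2 * np.pi * 5.0 * t)
        noise = pink_noise(rng, (2, n), fs, 1.0, 10.0)
        clean = noise + theta
        dirty = clean.copy()
        train = (5000 + 200 * np.arange(10)).astype(int)
        for s in train:
            dirty[:, s:s + 4] += 2000.0
        win = slice(5000, 10000)
        p_clean = band_power(clean[0, win], fs)
        p_dirty = band_power(dirty[0, win], fs)
        assert p_dirty > 2.0 * p_clean  # >100% inflation untreated

        rec = ContinuousRecording(dirty, fs, ["a", "b"])
        pulses = detect_tms_pulses(rec, threshold_sd=8.0)
        assert len(pulses) == 10
        out = replace_tms_artifacts(rec, pulses,
                                    rng=np.random.default_rng(9))
        p_fixed = band_power(out.samples[0, win], fs)
        assert abs(p_fixed - p_clean) / p_clean < 0.10

    def test_missing_reference_window_rejected(self):
        rec = _noise_recording()
        with pytest.raises(ValueError, match="reference"):
            replace_tms_artifacts(rec, PulseEventList(np.array([5]), "t", 8.0))


class TestFilter:
    def test_passband_5hz(self):
        fs = 1000.0
        t = np.arange(30000) / fs
        rec = ContinuousRecording(
            np.sin(2 * np.pi * 5.0 * t)[None, :], fs, ["a"])
        out = bandpass_filter(rec)
        interior = slice(5000, 25000)
        ratio = (out.samples[0, interior].std()
                 / rec.samples[0, interior].std())
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_80hz(self):
        fs = 500.0
        t = np.arange(20000) / fs
        rec = ContinuousRecording(
            np.sin(2 * np.pi * 80.0 * t)[None, :], fs, ["a"])
        out = bandpass_filter(rec, 0.3, 50.0)
        interior = slice(4000, 16000)
        atten = 20 * np.log10(
            rec.samples[0, interior].std() / out.samples[0, interior].std())
        assert atten >= 20.0

    def test_dc_rejection(self):
        rec = ContinuousRecording(np.full((1, 20000), 100.0), 1000.0, ["a"])
        out = bandpass_filter(rec)
        assert abs(out.samples.mean()) < 1e-6

    def test_inverted_edges_rejected(self):
        rec = _noise_recording()
        with pytest.raises(ValueError):
            bandpass_filter(rec, 50.0, 0.3)

    def test_high_edge_above_nyquist_rejected(self):
        rec = _noise_recording(fs=100.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, 0.3, 60.0)


class TestResample:
    def test_length_arithmetic(self):
        rec = ContinuousRecording(np.zeros((2, 13000)), 1000.0, ["a", "b"])
        out = resample(rec, 500.0)
        assert out.samples.shape == (2, 6500)
        assert out.sampling_rate == 500.0

    def test_identity(self):
        rec = _noise_recording()
        out = resample(rec, rec.sampling_rate)
        assert np.array_equal(out.samples, rec.samples)

    def test_5hz_amplitude_preserved(self):
        fs = 1000.0
        t = np.arange(20000) / fs
        rec = ContinuousRecording(
            np.sin(2 * np.pi * 5.0 * t)[None, :], fs, ["a"])
        out = resample(rec, 500.0)
        interior = slice(2000, 8000)
        assert (out.samples[0, interior].std()
                == pytest.approx(np.sqrt(0.5), rel=0.01))

    def test_event_rescaling(self):
        rec = ContinuousRecording(
            np.zeros((1, 10000)), 1000.0, ["a"],
            events=[Event("Stimulus", 5001, "")],
        )
        out = resample(rec, 500.0)
        assert out.events[0].onset == 2500  # rounded to nearest new sample

    def test_invalid_target(self):
        rec = _noise_recording()
        with pytest.raises(ValueError):
            resample(rec, -1.0)
        with pytest.raises(ValueError):
            resample(rec, 2000.0)


class TestRereference:
    def _epochs(self, data):
        data = np.asarray(data, dtype=float)
        times = np.arange(data.shape[2]) * 2.0
        return EpochedRecording(
            data, times, 500.0,
            [f"ch{i}" for i in range(data.shape[1])],
            pd.DataFrame({"trial": range(data.shape[0])}),
        )

    def test_balanced_pair_unchanged(self):
        ep = self._epochs([[[1.0, 1.0], [-1.0, -1.0]]])
        out = rereference_average(ep)
        assert np.array_equal(out.data, ep.data)

    def test_equal_channels_zeroed(self):
        ep = self._epochs(np.full((2, 3, 4), 5.0))
        out = rereference_average(ep)
        assert np.all(out.data == 0.0)

    def test_mean_zero_to_machine_precision(self):
        rng = np.random.default_rng(0)
        ep = self._epochs(rng.normal(size=(3, 5, 100)))
        out = rereference_average(ep)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-12


class TestReject:
    def _epochs_with_peaks(self, peaks):
        n_trials = len(peaks)
        data = np.zeros((n_trials, 2, 10))
        for i, p in enumerate(peaks):
            data[i, 1, 3] = p
        times = np.arange(10.0)
        return EpochedRecording(
            data, times, 1000.0, ["good", "bad"],
            pd.DataFrame({"trial": range(n_trials)}),
        )

    def test_below_threshold_kept(self):
        ep = self._epochs_with_peaks([249.0])
        out, log = reject_amplitude(ep)
        assert out.n_trials == 1
        assert log.n_dropped == 0

    def test_spike_dropped_with_channel_named(self):
        ep = self._epochs_with_peaks([300.0, 100.0])
        out, log = reject_amplitude(ep)
        assert out.n_trials == 1
        dropped = log.table[~log.table.kept]
        assert list(dropped["channel"]) == ["bad"]
        assert dropped["peak_uv"].iloc[0] == 300.0

    def test_exactly_threshold_kept(self):
        ep = self._epochs_with_peaks([250.0])
        out, _ = reject_amplitude(ep)
        assert out.n_trials == 1

    def test_all_rejected_warns_not_fatal(self, caplog):
        ep = self._epochs_with_peaks([400.0, 500.0])
        with caplog.at_level("WARNING"):
            out, log = reject_amplitude(ep)
        assert out.n_trials == 0
        assert log.n_dropped == 2


class TestChain:
    def test_chain_noop_without_pulses(self, montage62, profile,
                                       small_protocol):
        """Theta power after the full chain ~ filter+resample only, when no
        artifact is present (replacement is a no-op)."""
        from thetatrain.synthetic import SimulationConfig, \
            simulate_session_recording
        cfg = SimulationConfig(sampling_rate=1000.0, seed=21)
        rec, meta = simulate_session_recording(
            profile, small_protocol, None, montage62, cfg)

        full, _, _ = run_preprocessing(
            rec.copy(), meta, schedule=None, has_tms=True, seed=3)
        bare, _, _ = run_preprocessing(
            rec.copy(), meta, schedule=None, has_tms=False, seed=3)
        ch = full.channel_labels.index("Pz")
        win_full = full.data[:, ch, full.time_mask((5000.0, 10000.0))]
        win_bare = bare.data[:, ch, bare.time_mask((5000.0, 10000.0))]
        p_full = band_power(win_full, 500.0).mean()
        p_bare = band_power(win_bare, 500.0).mean()
        assert abs(p_full - p_bare) / p_bare < 0.05

    def test_chain_provenance(self, montage62, profile):
        from thetatrain.synthetic import (
            SimulationConfig, build_protocol, schedule_tms,
            simulate_session_recording,
        )
        proto = build_protocol(1, 2, 1, seed=5)
        sched = schedule_tms(proto)
        cfg = SimulationConfig(sampling_rate=1000.0, seed=22)
        rec, meta = simulate_session_recording(
            profile, proto, sched, montage62, cfg)
        epochs, log, prov = run_preprocessing(
            rec, meta, schedule=sched, seed=4)
        assert prov["n_pulses"] == 20
        assert prov["detection_method"] == "scheduled"
        assert epochs.sampling_rate == 500.0
        assert epochs.n_trials + log.n_dropped == 2
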