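"""Synthetic protocols, pulse trains, behavior, and TMS-EEG epochs.

Everything downstream of this module (artifact removal, time-frequency
analysis, cluster statistics, behavioral statistics) is exercised on data
produced here, with known ground-truth effect parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_brainvision import (
    ChannelMontage,
    ContinuousRecording,
    EpochedRecording,
    Event,
)

__all__ = [
    "TrialSpec",
    "SessionProtocol",
    "StimSchedule",
    "SubjectProfile",
    "CohortEffects",
    "SimulationConfig",
    "build_protocol",
    "schedule_tms",
    "simulate_cohort",
    "simulate_responses",
    "simulate_epochs",
    "simulate_session_recording",
    "pink_noise",
]

MANIPULATION_CUES = ("132", "213", "231", "312", "321")
SIMPLE_CUE = "123"


@dataclass(frozen=True)
class TrialSpec:
    trial_type: str  # "simple" | "manipulation"
    cue: str
    is_match: bool


@dataclass
class SessionProtocol:
    """Trial sequence and within-trial event timing for one session."""

    runs: int
    trials_per_run: int
    trials: list[TrialSpec]  # flattened, run-major
    cue_onset_ms: float = 5000.0
    probe_onset_ms: float = 10000.0
    trial_duration_ms: float = 15000.0

    def __post_init__(self) -> None:
        if len(self.trials) != self.runs * self.trials_per_run:
            raise ValueError("trial list does not match runs x trials_per_run")
        for spec in self.trials:
            if spec.trial_type == "simple" and spec.cue != SIMPLE_CUE:
                raise ValueError("simple trials must carry cue '123'")
            if spec.trial_type == "manipulation" and spec.cue == SIMPLE_CUE:
                raise ValueError("manipulation trials must not carry cue '123'")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_manipulation(self) -> int:
        return sum(t.trial_type == "manipulation" for t in self.trials)

    @property
    def n_simple(self) -> int:
        return sum(t.trial_type == "simple" for t in self.trials)

    def run_of(self, trial: int) -> int:
        return trial // self.trials_per_run + 1


def build_protocol(
    runs: int = 3,
    trials_per_run: int = 42,
    n_simple: int = 14,
    match_ratio: float = 0.5,
    seed: int | None = None,
) -> SessionProtocol:
    """Build a session protocol of ``runs`` runs, shuffled within run.

    Each run holds ``n_simple`` simple trials (cue "123") and the remainder
    manipulation trials with cues drawn from the non-identity orderings.
    Match/mismatch labels are balanced to ``match_ratio`` within each trial
    type of each run.
    """
    if runs < 1 or trials_per_run < 1 or n_simple < 0:
        raise ValueError("counts must be positive (n_simple may be 0)")
    if n_simple > trials_per_run:
        raise ValueError("n_simple cannot exceed trials_per_run")
    rng = np.random.default_rng(seed)
    n_manip = trials_per_run - n_simple

    trials: list[TrialSpec] = []
    for _ in range(runs):
        run_trials: list[TrialSpec] = []
        for trial_type, n in (("simple", n_simple), ("manipulation", n_manip)):
            n_match = int(round(n * match_ratio))
            matches = np.zeros(n, dtype=bool)
            matches[:n_match] = True
            rng.shuffle(matches)
            for m in matches:
                cue = (
                    SIMPLE_CUE
                    if trial_type == "simple"
                    else str(rng.choice(MANIPULATION_CUES))
                )
                run_trials.append(TrialSpec(trial_type, cue, bool(m)))
        order = rng.permutation(len(run_trials))
        trials.extend(run_trials[i] for i in order)
    return SessionProtocol(runs, trials_per_run, trials)


@dataclass
class StimSchedule:
    """One pulse train per trial, aligned to the cue onset."""

    pulse_onsets_ms: np.ndarray  # (n_trials, n_pulses), relative to tone onset
    freq_hz: float
    n_pulses: int

    @property
    def n_trials(self) -> int:
        return self.pulse_onsets_ms.shape[0]

    @property
    def total_pulses(self) -> int:
        return int(self.pulse_onsets_ms.size)

    @property
    def train_onsets_ms(self) -> np.ndarray:
        """Pulse times within one trial (identical across trials)."""
        return self.pulse_onsets_ms[0]


def schedule_tms(
    protocol: SessionProtocol, freq_hz: float = 5.0, n_pulses: int = 10
) -> StimSchedule:
    """Schedule one ``n_pulses``-pulse train at ``freq_hz`` per trial.

    Pulse ``k`` lands at ``cue_onset + k * 1000/freq_hz`` ms.  A train that
    overruns the probe onset triggers a warning, not an error.
    """
    if freq_hz <= 0:
        raise ValueError("freq_hz must be positive")
    if n_pulses < 1:
        raise ValueError("n_pulses must be at least 1")
    train = protocol.cue_onset_ms + np.arange(n_pulses) * 1000.0 / freq_hz
    if train[-1] >= protocol.probe_onset_ms:
        warnings.warn(
            f"pulse train ends at {train[-1]:.0f} ms, at or beyond the probe "
            f"onset ({protocol.probe_onset_ms:.0f} ms)",
            stacklevel=2,
        )
    onsets = np.tile(train, (protocol.n_trials, 1))
    return StimSchedule(onsets, freq_hz, n_pulses)


@dataclass
class SubjectProfile:
    """Ground-truth generative parameters for one simulated participant."""

    subject_id: str
    group: str  # "rhTMS" | "sham"
    baseline_dprime_manip: float
    baseline_dprime_simple: float
    slope_manip: float  # d' units per session
    slope_simple: float
    theta_gain: float  # theta burst amplitude, uV
    entrainment_gain: float  # extra amplitude under stimulation, uV
    seed: int
    lasting_gain: float = 0.0  # extra amplitude persisting post-training, uV

    def __post_init__(self) -> None:
        if self.group not in ("rhTMS", "sham"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "sham" and (
            self.entrainment_gain != 0 or self.lasting_gain != 0
        ):
            raise ValueError("sham profiles must have zero stimulation gains")
        if self.theta_gain < 0:
            raise ValueError("theta gain must be non-negative")
        if not np.isfinite(self.baseline_dprime_manip):
            raise ValueError("baseline d' must be finite")

    def dprime(self, session: int, trial_type: str) -> float:
        base, slope = (
            (self.baseline_dprime_manip, self.slope_manip)
            if trial_type == "manipulation"
            else (self.baseline_dprime_simple, self.slope_simple)
        )
        return max(0.0, base + slope * (session - 1))


@dataclass
class CohortEffects:
    """Population parameters from which subject profiles are drawn."""

    baseline_dprime_manip_mean: float = 1.7
    baseline_dprime_manip_sd: float = 0.4
    baseline_dprime_simple_mean: float = 2.9
    baseline_dprime_simple_sd: float = 0.4
    sham_slope_mean: float = 0.0
    slope_diff: float = 0.2  # rhTMS minus sham, d' per session
    slope_sd: float = 0.05
    theta_gain_mean: float = 3.0  # uV
    theta_gain_sd: float = 0.5
    entrainment_gain_mean: float = 2.0  # uV, rhTMS only
    entrainment_gain_sd: float = 0.3
    lasting_gain_mean: float = 1.0  # uV, rhTMS only, post-training sessions
    lasting_gain_sd: float = 0.2

    @classmethod
    def null(cls) -> "CohortEffects":
        return cls(slope_diff=0.0, entrainment_gain_mean=0.0,
                   entrainment_gain_sd=0.0, lasting_gain_mean=0.0,
                   lasting_gain_sd=0.0)


def simulate_cohort(
    n_per_group: int,
    effects: CohortEffects | None = None,
    seed: int | None = None,
    balance_tol: float = 0.25,
    max_retries: int = 100,
) -> list[SubjectProfile]:
    """Draw ``2 * n_per_group`` profiles balanced on baseline d'.

    Baselines are drawn for the whole cohort, rank-sorted, and assigned to
    groups in alternating pairs (ABBA), then the balance on mean baseline
    manipulation d' is checked against ``balance_tol``; the draw is retried
    up to ``max_retries`` times before failing.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be at least 1")
    effects = effects or CohortEffects()
    master = np.random.default_rng(seed)
    n = 2 * n_per_group
    for _ in range(max_retries):
        base_m = master.normal(
            effects.baseline_dprime_manip_mean,
            effects.baseline_dprime_manip_sd, n,
        )
        order = np.argsort(base_m)
        groups = np.empty(n, dtype=object)
        # ABBA assignment down the sorted baselines balances the means
        pattern = ["rhTMS", "sham", "sham", "rhTMS"]
        for rank, idx in enumerate(order):
            groups[idx] = pattern[rank % 4]
        mean_rh = base_m[groups == "rhTMS"].mean()
        mean_sh = base_m[groups == "sham"].mean()
        if abs(mean_rh - mean_sh) <= balance_tol:
            break
    else:
        raise RuntimeError(
            f"could not balance baseline d' within {balance_tol} "
            f"after {max_retries} draws"
        )

    profiles = []
    seeds = np.random.SeedSequence(
        master.integers(2**31)
    ).spawn(n)
    for i in range(n):
        group = str(groups[i])
        slope = master.normal(effects.sham_slope_mean, effects.slope_sd)
        entrain = 0.0
        lasting = 0.0
        if group == "rhTMS":
            slope += effects.slope_diff
            entrain = max(
                0.0,
                master.normal(effects.entrainment_gain_mean,
                              effects.entrainment_gain_sd),
            )
            lasting = max(
                0.0,
                master.normal(effects.lasting_gain_mean,
                              effects.lasting_gain_sd),
            )
        profiles.append(SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            group=group,
            baseline_dprime_manip=float(base_m[i]),
            baseline_dprime_simple=float(master.normal(
                effects.baseline_dprime_simple_mean,
                effects.baseline_dprime_simple_sd,
            )),
            slope_manip=float(slope),
            slope_simple=0.0,
            theta_gain=float(max(0.0, master.normal(
                effects.theta_gain_mean, effects.theta_gain_sd))),
            entrainment_gain=float(entrain),
            seed=int(seeds[i].generate_state(1)[0] % (2**31)),
            lasting_gain=float(lasting),
        ))
    return profiles


def simulate_responses(
    profile: SubjectProfile,
    protocol: SessionProtocol,
    session: int,
    rng: np.random.Generator,
    criterion: float = 0.0,
) -> pd.DataFrame:
    """Simulate per-trial responses from an equal-variance Gaussian observer.

    The decision variable is N(+d'/2, 1) on mismatch ("signal") trials and
    N(-d'/2, 1) on match trials; the observer responds "mismatch" when it
    exceeds ``criterion``.  Sensitivity follows the profile's learning line
    ``baseline + slope * (session - 1)``, floored at zero.
    """
    if not 1 <= session <= 7:
        raise ValueError("session must be in 1..7")
    n = protocol.n_trials
    trial_type = np.array([s.trial_type for s in protocol.trials])
    is_match = np.array([s.is_match for s in protocol.trials])
    d = np.where(
        trial_type == "manipulation",
        profile.dprime(session, "manipulation"),
        profile.dprime(session, "simple"),
    )
    loc = np.where(is_match, -d / 2.0, d / 2.0)
    evidence = rng.normal(loc, 1.0)
    response = np.where(evidence > criterion, "mismatch", "match")
    correct = (response == "mismatch") == ~is_match
    idx = np.arange(n)
    return pd.DataFrame({
        "subject": profile.subject_id,
        "group": profile.group,
        "session": session,
        "run": idx // protocol.trials_per_run + 1,
        "trial": idx,
        "trial_type": trial_type,
        "cue": [s.cue for s in protocol.trials],
        "is_match": is_match,
        "response": response,
        "correct": correct,
    })


@dataclass
class SimulationConfig:
    """Physical parameters of the EEG simulator."""

    n_channels: int = 62
    sampling_rate: float = 1000.0
    noise_exponent: float = 1.0  # 1/f^beta background
    noise_amplitude_uv: float = 10.0  # background SD
    theta_freq_hz: float = 5.0
    target_channels: tuple[str, ...] = (
        "P7", "P5", "P3", "P1", "Pz", "CP1", "CP2", "CP3",
    )
    tms_amplitude_uv: float = 2000.0
    tms_width_ms: float = 4.0
    tms_decay_ms: float = 8.0
    ramp_ms: float = 200.0  # raised-cosine onset/offset of theta bursts
    epoch_window_ms: tuple[float, float] = (-1000.0, 12000.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate < 500:
            raise ValueError("sampling rate must be at least 500 Hz")
        for name in ("noise_amplitude_uv", "tms_amplitude_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def pink_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    fs: float,
    exponent: float = 1.0,
    amplitude: float = 1.0,
) -> np.ndarray:
    """1/f^exponent noise along the last axis, scaled to the given SD."""
    n = shape[-1]
    if amplitude == 0 or n == 0:
        return np.zeros(shape)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = (
        rng.normal(size=shape[:-1] + (freqs.size,))
        + 1j * rng.normal(size=shape[:-1] + (freqs.size,))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * amplitude


def _tms_waveform(fs: float, width_ms: float, decay_ms: float) -> np.ndarray:
    """Biphasic transient followed by an exponential tail; unit peak."""
    n_bi = max(2, int(round(width_ms * fs / 1000.0)))
    t_bi = np.arange(n_bi) / n_bi
    biphasic = np.sin(2.0 * np.pi * t_bi)
    n_tail = int(round(3 * decay_ms * fs / 1000.0))
    tail = 0.3 * np.exp(-np.arange(n_tail) / (decay_ms * fs / 1000.0))
    w = np.concatenate([biphasic, tail])
    return w / np.max(np.abs(w))


def _theta_burst(
    times_ms: np.ndarray,
    freq_hz: float,
    amplitude: float,
    window_ms: tuple[float, float],
    ramp_ms: float,
    phase: float,
) -> np.ndarray:
    lo, hi = window_ms
    env = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms < hi)
    env[inside] = 1.0
    if ramp_ms > 0:
        up = inside & (times_ms < lo + ramp_ms)
        env[up] = 0.5 * (1 - np.cos(np.pi * (times_ms[up] - lo) / ramp_ms))
        down = inside & (times_ms >= hi - ramp_ms)
        env[down] = 0.5 * (1 - np.cos(np.pi * (hi - times_ms[down]) / ramp_ms))
    return amplitude * env * np.sin(
        2.0 * np.pi * freq_hz * times_ms / 1000.0 + phase
    )


def _artifact_channel_scale(
    montage: ChannelMontage, target_idx: np.ndarray
) -> np.ndarray:
    """Artifact gain per channel: 1 at the coil, decaying with distance."""
    if target_idx.size == 0:
        return np.ones(len(montage))
    coil = montage.positions[target_idx].mean(axis=0)
    dist = np.linalg.norm(montage.positions - coil, axis=1)
    return 0.3 + 0.7 * np.exp(-dist / 60.0)


def _render_trial(
    rng: np.random.Generator,
    times_ms: np.ndarray,
    spec: TrialSpec,
    montage: ChannelMontage,
    config: SimulationConfig,
    theta_amplitude: float,
    pulse_onsets_ms: np.ndarray | None,
    window_ms: tuple[float, float],
) -> np.ndarray:
    n_ch = len(montage)
    fs = config.sampling_rate
    data = pink_noise(
        rng, (n_ch, times_ms.size), fs,
        config.noise_exponent, config.noise_amplitude_uv,
    )
    target_idx = np.array(
        [montage.index(l) for l in config.target_channels if l in montage.labels],
        dtype=int,
    )
    if spec.trial_type == "manipulation" and theta_amplitude > 0:
        burst = _theta_burst(
            times_ms, config.theta_freq_hz, theta_amplitude,
            window_ms, config.ramp_ms, rng.uniform(0, 2 * np.pi),
        )
        data[target_idx] += burst
    if pulse_onsets_ms is not None and config.tms_amplitude_uv > 0:
        wave = _tms_waveform(fs, config.tms_width_ms, config.tms_decay_ms)
        scale = _artifact_channel_scale(montage, target_idx)
        t0 = times_ms[0]
        for onset in pulse_onsets_ms:
            s = int(round((onset - t0) * fs / 1000.0))
            if s < 0 or s >= times_ms.size:
                continue
            seg = wave[: times_ms.size - s]
            data[:, s:s + seg.size] += (
                config.tms_amplitude_uv * scale[:, None] * seg[None, :]
            )
    return data


def _trial_metadata(
    profile: SubjectProfile, protocol: SessionProtocol, session: int
) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "subject": profile.subject_id,
            "group": profile.group,
            "session": session,
            "run": protocol.run_of(i),
            "trial": i,
            "trial_type": spec.trial_type,
            "cue": spec.cue,
            "is_match": spec.is_match,
        }
        for i, spec in enumerate(protocol.trials)
    ])


def simulate_epochs(
    profile: SubjectProfile,
    protocol: SessionProtocol,
    schedule: StimSchedule | None,
    montage: ChannelMontage,
    config: SimulationConfig,
    session: int = 1,
) -> EpochedRecording:
    """Generate epoched EEG directly (no continuous intermediate).

    Manipulation trials carry a theta burst on the target channels over the
    manipulation window; when a ``schedule`` is present every pulse adds a
    brief high-amplitude transient on all channels (largest near the coil)
    and, for rhTMS subjects, the burst amplitude gains the profile's
    entrainment gain.
    """
    if len(montage) != config.n_channels:
        raise ValueError(
            f"montage has {len(montage)} channels, config expects "
            f"{config.n_channels}"
        )
    fs = config.sampling_rate
    lo, hi = config.epoch_window_ms
    n_times = int(round((hi - lo) * fs / 1000.0))
    times_ms = lo + np.arange(n_times) * 1000.0 / fs
    window = (protocol.cue_onset_ms, protocol.probe_onset_ms)

    amplitude = profile.theta_gain
    if schedule is not None and profile.group == "rhTMS":
        amplitude += profile.entrainment_gain
    if session >= 7 and profile.group == "rhTMS":
        amplitude += profile.lasting_gain

    rng = np.random.default_rng(
        config.seed if config.seed is not None else profile.seed
    )
    data = pink_noise(
        rng, (protocol.n_trials, len(montage), n_times), fs,
        config.noise_exponent, config.noise_amplitude_uv,
    )
    target_idx = np.array(
        [montage.index(l) for l in config.target_channels
         if l in montage.labels],
        dtype=int,
    )
    wave = _tms_waveform(fs, config.tms_width_ms, config.tms_decay_ms)
    art_scale = _artifact_channel_scale(montage, target_idx)
    for i, spec in enumerate(protocol.trials):
        if spec.trial_type == "manipulation" and amplitude > 0:
            burst = _theta_burst(
                times_ms, config.theta_freq_hz, amplitude,
                window, config.ramp_ms, rng.uniform(0, 2 * np.pi),
            )
            data[i][target_idx] += burst
        if schedule is not None and config.tms_amplitude_uv > 0:
            for onset in schedule.pulse_onsets_ms[i]:
                s = int(round((onset - times_ms[0]) * fs / 1000.0))
                if s < 0 or s >= n_times:
                    continue
                seg = wave[: n_times - s]
                data[i][:, s:s + seg.size] += (
                    config.tms_amplitude_uv * art_scale[:, None] * seg[None, :]
                )
    meta = _trial_metadata(profile, protocol, session)
    return EpochedRecording(data, times_ms, fs, list(montage.labels), meta)


def simulate_session_recording(
    profile: SubjectProfile,
    protocol: SessionProtocol,
    schedule: StimSchedule | None,
    montage: ChannelMontage,
    config: SimulationConfig,
    session: int = 1,
    inter_trial_gap_ms: float = 1500.0,
) -> tuple[ContinuousRecording, pd.DataFrame]:
    """Render a continuous recording with one Stimulus marker per trial.

    Returns the recording plus per-trial metadata (without responses; use
    :func:`simulate_responses` for the behavior table).
    """
    fs = config.sampling_rate
    spacing_ms = protocol.trial_duration_ms + inter_trial_gap_ms
    lead_ms = 2000.0
    n_total = int(round(
        (lead_ms + spacing_ms * protocol.n_trials) * fs / 1000.0
    ))
    rng = np.random.default_rng(
        config.seed if config.seed is not None else profile.seed
    )
    samples = pink_noise(
        rng, (len(montage), n_total), fs,
        config.noise_exponent, config.noise_amplitude_uv,
    )
    window = (protocol.cue_onset_ms, protocol.probe_onset_ms)
    amplitude = profile.theta_gain
    if schedule is not None and profile.group == "rhTMS":
        amplitude += profile.entrainment_gain
    if session >= 7 and profile.group == "rhTMS":
        amplitude += profile.lasting_gain

    events = []
    times_trial = np.arange(
        int(round(protocol.trial_duration_ms * fs / 1000.0))
    ) * 1000.0 / fs
    target_idx = np.array(
        [montage.index(l) for l in config.target_channels if l in montage.labels],
        dtype=int,
    )
    for i, spec in enumerate(protocol.trials):
        onset_ms = lead_ms + i * spacing_ms
        onset = int(round(onset_ms * fs / 1000.0))
        events.append(Event("Stimulus", onset, f"S{i + 1}"))
        if spec.trial_type == "manipulation" and amplitude > 0:
            burst = _theta_burst(
                times_trial, config.theta_freq_hz, amplitude,
                window, config.ramp_ms, rng.uniform(0, 2 * np.pi),
            )
            samples[target_idx, onset:onset + burst.size] += burst
        if schedule is not None and config.tms_amplitude_uv > 0:
            wave = _tms_waveform(fs, config.tms_width_ms, config.tms_decay_ms)
            scale = _artifact_channel_scale(montage, target_idx)
            for p_ms in schedule.pulse_onsets_ms[i]:
                s = onset + int(round(p_ms * fs / 1000.0))
                seg = wave[: n_total - s]
                samples[:, s:s + seg.size] += (
                    config.tms_amplitude_uv * scale[:, None] * seg[None, :]
                )
    recording = ContinuousRecording(
        samples, fs, list(montage.labels), "nose", events
    )
    return recording, _trial_metadata(profile, protocol, session)
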