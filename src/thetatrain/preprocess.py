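"""TMS artifact handling and the EEG preprocessing chain.

Chain order: detect pulses -> replace artifacts with reference-matched
Gaussian noise -> resample -> band-pass filter -> epoch -> average
re-reference -> amplitude-based trial rejection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.fft
import scipy.signal

from .io_brainvision import ContinuousRecording, EpochedRecording, Event, epoch
from .synthetic import StimSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "PulseEventList",
    "RejectionLog",
    "detect_tms_pulses",
    "replace_tms_artifacts",
    "bandpass_filter",
    "resample",
    "rereference_average",
    "reject_amplitude",
    "run_preprocessing",
]


@dataclass
class PulseEventList:
    """Detected TMS pulse peaks, as 0-based sample indices."""

    onsets: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets.size


@dataclass
class RejectionLog:
    """Per-trial keep/drop decisions from amplitude screening."""

    table: pd.DataFrame  # columns: trial, kept, channel, peak_uv
    threshold_uv: float

    @property
    def n_dropped(self) -> int:
        return int((~self.table["kept"]).sum())


def _robust_sd(x: np.ndarray) -> np.ndarray:
    """MAD-based SD estimate per channel."""
    med = np.median(x, axis=-1, keepdims=True)
    return 1.4826 * np.median(np.abs(x - med), axis=-1)


def detect_tms_pulses(
    recording: ContinuousRecording,
    threshold_sd: float = 8.0,
    schedule: StimSchedule | None = None,
) -> PulseEventList:
    """Locate TMS pulse peaks in a continuous recording.

    With a ``schedule``, scheduled onsets (relative to each Stimulus event)
    are refined to the local absolute-amplitude peak.  Without one, samples
    whose absolute amplitude exceeds ``threshold_sd`` robust SDs on any
    channel are flagged and flags closer than 20 ms are merged into one
    pulse whose onset is the peak sample.
    """
    if recording.n_samples == 0:
        raise ValueError("recording is empty")
    fs = recording.sampling_rate
    x = recording.samples

    if schedule is not None:
        half = int(round(5 * fs / 1000.0))  # +-5 ms search around schedule
        onsets = []
        stim_events = [ev for ev in recording.events if ev.type == "Stimulus"]
        for trial, ev in enumerate(stim_events):
            row = min(trial, schedule.pulse_onsets_ms.shape[0] - 1)
            for p_ms in schedule.pulse_onsets_ms[row]:
                s = ev.onset + int(round(p_ms * fs / 1000.0))
                lo, hi = max(0, s - half), min(recording.n_samples, s + half + 1)
                if lo >= hi:
                    continue
                peak = lo + int(np.argmax(np.max(np.abs(x[:, lo:hi]), axis=0)))
                onsets.append(peak)
        return PulseEventList(
            np.unique(onsets), method="scheduled", threshold=float("nan")
        )

    sd = _robust_sd(x)
    sd[sd == 0] = np.inf
    flags = np.flatnonzero(np.any(np.abs(x) > threshold_sd * sd[:, None], axis=0))
    if flags.size == 0:
        return PulseEventList(np.empty(0, dtype=int), "threshold", threshold_sd)

    merge_gap = int(round(20 * fs / 1000.0))
    groups = np.split(flags, np.flatnonzero(np.diff(flags) > merge_gap) + 1)
    onsets = []
    for g in groups:
        lo, hi = g[0], g[-1] + 1
        peak = lo + int(np.argmax(np.max(np.abs(x[:, lo:hi]), axis=0)))
        onsets.append(peak)
    return PulseEventList(np.array(onsets), "threshold", threshold_sd)


def replace_tms_artifacts(
    recording: ContinuousRecording,
    pulses: PulseEventList,
    pre_ms: float = 10.0,
    post_ms: float = 20.0,
    ref_window_ms: tuple[float, float] = (-35.0, -15.0),
    rng: np.random.Generator | None = None,
) -> ContinuousRecording:
    """Replace each pulse's span with reference-matched Gaussian noise.

    Per channel and pulse, samples in the closed span
    ``[peak - pre_ms, peak + post_ms]`` are replaced by independent Gaussian
    draws whose mean and SD match that channel's reference segment
    (``ref_window_ms`` relative to the peak, half-open).  If the reference
    window would overlap a previously replaced span, it is shifted earlier
    to the nearest clean window of equal length (logged).  All other samples
    are bit-identical to the input.
    """
    rng = rng or np.random.default_rng()
    out = recording.copy()
    if len(pulses) == 0:
        return out
    fs = recording.sampling_rate
    x = out.samples
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    ref_lo_off = int(round(ref_window_ms[0] * fs / 1000.0))
    ref_hi_off = int(round(ref_window_ms[1] * fs / 1000.0))
    replaced: list[tuple[int, int]] = []  # closed spans already overwritten

    for peak in pulses.onsets:
        lo = peak - pre
        hi = peak + post  # inclusive
        ref_lo = peak + ref_lo_off
        ref_hi = peak + ref_hi_off  # exclusive
        if ref_lo < 0:
            raise ValueError(
                f"pulse at sample {peak} lacks a full reference window"
            )
        # shift the reference window earlier until clear of replaced spans
        shifted = False
        while any(ref_lo <= r_hi and ref_hi - 1 >= r_lo for r_lo, r_hi in replaced):
            overlap_lo = min(
                r_lo for r_lo, r_hi in replaced
                if ref_lo <= r_hi and ref_hi - 1 >= r_lo
            )
            width = ref_hi - ref_lo
            ref_hi = overlap_lo
            ref_lo = ref_hi - width
            shifted = True
            if ref_lo < 0:
                raise ValueError(
                    f"no clean reference window before pulse at sample {peak}"
                )
        if shifted:
            logger.info(
                "pulse at sample %d: reference window shifted to [%d, %d)",
                peak, ref_lo, ref_hi,
            )
        ref = x[:, ref_lo:ref_hi]
        mean = ref.mean(axis=1)
        sd = ref.std(axis=1)
        span_lo = max(0, lo)
        span_hi = min(recording.n_samples - 1, hi)
        width = span_hi - span_lo + 1
        noise = rng.normal(size=(recording.n_channels, width))
        x[:, span_lo:span_hi + 1] = mean[:, None] + sd[:, None] * noise
        replaced.append((span_lo, span_hi))
    return out


def _fir_bandpass(
    low_hz: float, high_hz: float, fs: float, n_samples: int,
    trans_low: float = 0.3, trans_high: float = 12.5,
) -> np.ndarray:
    """Hamming-window linear-phase FIR band-pass kernel."""
    # Hamming transition width ~ 3.3 / numtaps (normalized)
    trans = min(trans_low, trans_high)
    numtaps = int(math.ceil(3.3 * fs / trans))
    numtaps |= 1  # odd length => symmetric, type-I
    max_taps = max(3, (n_samples // 3) | 1)
    if numtaps > max_taps:
        logger.warning(
            "shortening FIR from %d to %d taps for a %d-sample signal; "
            "the %g Hz edge will be shallower", numtaps, max_taps, n_samples,
            low_hz,
        )
        numtaps = max_taps
    return scipy.signal.firwin(
        numtaps, [low_hz, high_hz], pass_zero=False, fs=fs, window="hamming"
    )


def _zero_phase_apply(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR along the last axis with reflect padding."""
    pad = kernel.size // 2
    padded = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    n_lin = padded.shape[-1] + kernel.size - 1
    nfft = scipy.fft.next_fast_len(n_lin)
    spec = scipy.fft.rfft(padded, nfft, axis=-1)
    spec *= scipy.fft.rfft(kernel, nfft)
    full = scipy.fft.irfft(spec, nfft, axis=-1)[..., :n_lin]
    # centered ("same") slice of the linear convolution, then unpad
    start = (kernel.size - 1) // 2 + pad
    return full[..., start:start + x.shape[-1]]


def bandpass_filter(
    recording: ContinuousRecording,
    low_hz: float = 0.3,
    high_hz: float = 50.0,
) -> ContinuousRecording:
    """Zero-phase FIR band-pass; removes DC, <1% passband ripple."""
    if high_hz <= low_hz:
        raise ValueError("band edges inverted")
    if high_hz >= recording.sampling_rate / 2:
        raise ValueError("high edge must be below Nyquist")
    out = recording.copy()
    x = out.samples
    mean = x.mean(axis=1, keepdims=True)
    kernel = _fir_bandpass(low_hz, high_hz, recording.sampling_rate, x.shape[1])
    out.samples = _zero_phase_apply(x - mean, kernel)
    return out


def resample(
    recording: ContinuousRecording, target_hz: float = 500.0
) -> ContinuousRecording:
    """Polyphase anti-aliased resampling; event onsets are rescaled."""
    if target_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_hz > recording.sampling_rate:
        raise ValueError("target rate must not exceed the current rate")
    if target_hz == recording.sampling_rate:
        return recording.copy()
    frac = Fraction(target_hz / recording.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    samples = scipy.signal.resample_poly(recording.samples, up, down, axis=1)
    ratio = target_hz / recording.sampling_rate
    events = [
        Event(ev.type, int(round(ev.onset * ratio)), ev.description)
        for ev in recording.events
        if int(round(ev.onset * ratio)) < samples.shape[1]
    ]
    return ContinuousRecording(
        samples, target_hz, list(recording.channel_labels),
        recording.reference, events,
    )


def rereference_average(epochs: EpochedRecording) -> EpochedRecording:
    """Subtract the per-sample mean over scalp channels."""
    if epochs.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = epochs.copy()
    out.data = out.data - out.data.mean(axis=1, keepdims=True)
    return out


def reject_amplitude(
    epochs: EpochedRecording, threshold_uv: float = 250.0
) -> tuple[EpochedRecording, RejectionLog]:
    """Drop trials whose absolute amplitude strictly exceeds the threshold.

    A value of exactly ``threshold_uv`` is kept.  The log records, for each
    trial, the worst channel and its peak absolute value.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    rows = []
    keep = np.ones(epochs.n_trials, dtype=bool)
    for i in range(epochs.n_trials):
        absmax_per_ch = np.max(np.abs(epochs.data[i]), axis=1)
        worst = int(np.argmax(absmax_per_ch))
        peak = float(absmax_per_ch[worst])
        kept = peak <= threshold_uv
        keep[i] = kept
        rows.append({
            "trial": i,
            "kept": kept,
            "channel": epochs.channel_labels[worst],
            "peak_uv": peak,
        })
    log = RejectionLog(pd.DataFrame(rows), threshold_uv)
    if not keep.any():
        logger.warning("all %d trials exceeded +-%g uV", epochs.n_trials,
                       threshold_uv)
    return epochs.select_trials(keep), log


def run_preprocessing(
    recording: ContinuousRecording,
    metadata: pd.DataFrame | None = None,
    schedule: StimSchedule | None = None,
    has_tms: bool = True,
    window_ms: tuple[float, float] = (-1000.0, 12000.0),
    target_hz: float = 500.0,
    band_hz: tuple[float, float] = (0.3, 50.0),
    threshold_uv: float = 250.0,
    detect_threshold_sd: float = 8.0,
    seed: int | None = None,
    ica_hook=None,
) -> tuple[EpochedRecording, RejectionLog, dict]:
    """Run the full chain on one continuous recording.

    ``ica_hook``, when given, is called with the filtered recording and must
    return a recording of the same shape; the default is a pass-through (no
    ICA is implemented here).  Returns epochs, the rejection log, and a
    provenance dict.
    """
    prov: dict = {
        "has_tms": has_tms, "target_hz": target_hz, "band_hz": band_hz,
        "threshold_uv": threshold_uv, "seed": seed,
    }
    rec = recording
    if has_tms:
        pulses = detect_tms_pulses(rec, detect_threshold_sd, schedule)
        rec = replace_tms_artifacts(
            rec, pulses, rng=np.random.default_rng(seed)
        )
        prov["n_pulses"] = len(pulses)
        prov["detection_method"] = pulses.method
    rec = resample(rec, target_hz)
    rec = bandpass_filter(rec, *band_hz)
    if ica_hook is not None:
        rec = ica_hook(rec)
        prov["ica"] = getattr(ica_hook, "__name__", "custom")
    else:
        prov["ica"] = "pass-through"
    epochs = epoch(rec, "Stimulus", window_ms, metadata)
    epochs = rereference_average(epochs)
    epochs, log = reject_amplitude(epochs, threshold_uv)
    prov["n_trials_kept"] = epochs.n_trials
    prov["n_trials_dropped"] = log.n_dropped
    return epochs, log, prov
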