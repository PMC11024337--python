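"""Morlet time-frequency maps, theta Hilbert envelopes, and
power-behavior correlation maps.

Magnitudes are computed per trial and then averaged across trials, so both
phase-locked and induced activity contribute.  Baseline normalization is a
per-bin z-score against a pre-stimulus window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.signal

from .io_brainvision import EpochedRecording
from .preprocess import _fir_bandpass, _zero_phase_apply

logger = logging.getLogger(__name__)

__all__ = [
    "TFRMap",
    "BandEnvelope",
    "CorrelationMap",
    "morlet_tfr",
    "zscore_baseline",
    "band_envelope",
    "theta_topography",
    "tf_behavior_correlation",
]

THETA_BAND = (4.0, 8.0)
MANIPULATION_WINDOW_MS = (5000.0, 10000.0)
BASELINE_WINDOW_MS = (-1000.0, 0.0)


@dataclass
class TFRMap:
    """Trial-averaged oscillatory magnitude: channels x freqs x times."""

    magnitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_labels: list[str]
    ratio: float
    normalization: str = "raw"  # "raw" | "zscore"
    baseline_ms: tuple[float, float] | None = None
    # per-frequency time span (ms) contaminated by convolution edges
    edge_ms: np.ndarray = field(default_factory=lambda: np.empty(0))

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        return (self.times >= lo) & (self.times < hi)

    def window_average(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Mean over a half-open time window: channels x freqs."""
        return self.magnitude[:, :, self.time_mask(window_ms)].mean(axis=2)


@dataclass
class BandEnvelope:
    """Trial-averaged band-limited Hilbert envelope: channels x times."""

    envelope: np.ndarray
    band: tuple[float, float]
    times: np.ndarray
    channel_labels: list[str]
    normalization: str = "raw"
    baseline_ms: tuple[float, float] | None = None

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        lo, hi = window_ms
        return (self.times >= lo) & (self.times < hi)

    def window_topography(
        self, window_ms: tuple[float, float] = MANIPULATION_WINDOW_MS
    ) -> np.ndarray:
        """Per-channel mean over a half-open time window."""
        return self.envelope[:, self.time_mask(window_ms)].mean(axis=1)


@dataclass
class CorrelationMap:
    """Across-subject Pearson r per bin (channels x ... x times)."""

    r: np.ndarray
    n_subjects: int
    covariate: str

    def peak(self) -> tuple[float, tuple[int, ...]]:
        idx = np.unravel_index(int(np.nanargmax(self.r)), self.r.shape)
        return float(self.r[idx]), idx


def _morlet_kernel(f0: float, ratio: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet at f0 with sigma_f = f0/ratio.

    Normalized so the analytic magnitude of a unit-amplitude sinusoid at f0
    is ~1.
    """
    sigma_f = f0 / ratio
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    half = int(np.ceil(5.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    kernel = gauss * np.exp(2j * np.pi * f0 * t)
    # unit DC gain of the envelope, x2 to recover real-signal amplitude
    return 2.0 * kernel / gauss.sum()


def morlet_tfr(
    epochs: EpochedRecording,
    freqs: np.ndarray | None = None,
    ratio: float = 7.0,
    channels: list[str] | None = None,
) -> TFRMap:
    """Complex Morlet decomposition, magnitude averaged across trials.

    The wavelet family is parameterized by ``f0 / sigma_f = ratio``; at each
    f0, ``sigma_t = 1 / (2 pi sigma_f)``.  Edges are mirror-padded; the
    per-frequency edge extent (3 sigma_t, in ms) is reported in ``edge_ms``.
    """
    fs = epochs.sampling_rate
    if freqs is None:
        freqs = np.arange(1.0, 81.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")

    if channels is None:
        ch_idx = np.arange(epochs.n_channels)
        labels = list(epochs.channel_labels)
    else:
        ch_idx = np.array([epochs.channel_labels.index(c) for c in channels])
        labels = list(channels)

    data = epochs.data[:, ch_idx, :]  # trials x channels x time
    n_times = data.shape[-1]
    out = np.zeros((len(ch_idx), freqs.size, n_times))
    edge_ms = np.zeros(freqs.size)
    for fi, f0 in enumerate(freqs):
        kernel = _morlet_kernel(f0, ratio, fs)
        sigma_t = ratio / (2.0 * np.pi * f0)
        edge_ms[fi] = 3.0 * sigma_t * 1000.0
        if kernel.size // 2 >= n_times:
            raise ValueError(
                f"epoch too short to resolve {f0} Hz at ratio {ratio}"
            )
        pad = kernel.size // 2
        padded = np.pad(data, [(0, 0), (0, 0), (pad, pad)], mode="reflect")
        conv = scipy.signal.fftconvolve(
            padded, kernel.reshape(1, 1, -1), mode="same", axes=-1
        )[..., pad:-pad]
        out[:, fi, :] = np.abs(conv).mean(axis=0)
    return TFRMap(
        out, freqs, epochs.times.copy(), labels, ratio, edge_ms=edge_ms
    )


def zscore_baseline(
    tfr_or_env: TFRMap | BandEnvelope,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
):
    """Z-score per channel (x frequency) against the baseline window.

    Bins with zero baseline SD are set to 0 and logged.  Returns a new
    object of the same type tagged ``normalization="zscore"``.
    """
    mask = tfr_or_env.time_mask(baseline_ms)
    if not mask.any():
        raise ValueError("baseline window lies outside the epoch")
    if isinstance(tfr_or_env, TFRMap):
        values = tfr_or_env.magnitude
    else:
        values = tfr_or_env.envelope
    base = values[..., mask]
    mean = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, keepdims=True)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d bins have zero baseline SD; their z-scores are set to 0",
            int(degenerate.sum()),
        )
    sd_safe = np.where(degenerate, 1.0, sd)
    z = (values - mean) / sd_safe
    z = np.where(np.broadcast_to(degenerate, z.shape), 0.0, z)

    if isinstance(tfr_or_env, TFRMap):
        return TFRMap(
            z, tfr_or_env.freqs.copy(), tfr_or_env.times.copy(),
            list(tfr_or_env.channel_labels), tfr_or_env.ratio,
            normalization="zscore", baseline_ms=baseline_ms,
            edge_ms=tfr_or_env.edge_ms.copy(),
        )
    return BandEnvelope(
        z, tfr_or_env.band, tfr_or_env.times.copy(),
        list(tfr_or_env.channel_labels),
        normalization="zscore", baseline_ms=baseline_ms,
    )


def band_envelope(
    epochs: EpochedRecording, band: tuple[float, float] = THETA_BAND
) -> BandEnvelope:
    """Zero-phase band-pass then Hilbert magnitude, averaged over trials."""
    fs = epochs.sampling_rate
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, Nyquist)")
    kernel = _fir_bandpass(lo, hi, fs, epochs.data.shape[-1],
                           trans_low=min(2.0, lo), trans_high=2.0)
    filtered = _zero_phase_apply(epochs.data, kernel)
    # zero-pad to a fast FFT length; the pad only perturbs the last samples
    n = filtered.shape[-1]
    nfft = scipy.fft.next_fast_len(n)
    analytic = scipy.signal.hilbert(filtered, N=nfft, axis=-1)[..., :n]
    env = np.abs(analytic).mean(axis=0)
    return BandEnvelope(env, band, epochs.times.copy(),
                        list(epochs.channel_labels))


def theta_topography(
    epochs: EpochedRecording,
    band: tuple[float, float] = THETA_BAND,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS,
    window_ms: tuple[float, float] = MANIPULATION_WINDOW_MS,
) -> np.ndarray:
    """Per-channel baseline z-scored band envelope averaged over a window.

    Convenience composition of :func:`band_envelope`,
    :func:`zscore_baseline` and window averaging — one scalar per channel.
    """
    env = zscore_baseline(band_envelope(epochs, band), baseline_ms)
    return env.window_topography(window_ms)


def tf_behavior_correlation(
    subject_maps: list[TFRMap] | list[np.ndarray],
    behavior: np.ndarray,
    covariate: str = "dprime",
) -> CorrelationMap:
    """Pearson r across subjects at every bin of the subject maps."""
    behavior = np.asarray(behavior, dtype=float)
    if len(subject_maps) < 3:
        raise ValueError("need at least 3 subjects")
    if len(subject_maps) != behavior.size:
        raise ValueError("one behavior value per subject map is required")
    if np.std(behavior) == 0:
        raise ValueError("behavior vector has zero variance")
    arrays = [
        m.magnitude if isinstance(m, TFRMap) else np.asarray(m, dtype=float)
        for m in subject_maps
    ]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("subject maps must share shape")
    stack = np.stack(arrays)  # subjects x bins...
    n = stack.shape[0]
    xm = stack - stack.mean(axis=0)
    ym = (behavior - behavior.mean()).reshape((n,) + (1,) * (stack.ndim - 1))
    cov = (xm * ym).sum(axis=0)
    denom = np.sqrt((xm ** 2).sum(axis=0) * (ym ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMap(r, n, covariate)
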