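"""BrainVision-dialect I/O, montage loading, and epoching.

The reader/writer pair supports the single dialect produced by BrainAmp
exports and by :func:`write_brainvision`: INT16, multiplexed, little-endian
binary with an INI-style ``.vhdr`` header and ``.vmrk`` marker file.
Anything else is rejected with a named error rather than guessed at.
"""

from __future__ import annotations

import io as _io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Event",
    "ContinuousRecording",
    "ChannelMontage",
    "EpochedRecording",
    "MissingCompanionFileError",
    "UnsupportedFormatError",
    "ChannelCountMismatchError",
    "DuplicateLabelError",
    "read_brainvision",
    "write_brainvision",
    "load_montage",
    "epoch",
    "save_epochs",
    "load_epochs",
]


class MissingCompanionFileError(FileNotFoundError):
    """A .vhdr references a .eeg or .vmrk file that does not exist."""


class UnsupportedFormatError(ValueError):
    """The header declares a binary layout this reader does not support."""


class ChannelCountMismatchError(ValueError):
    """Binary payload size is inconsistent with the declared channel count."""


class DuplicateLabelError(ValueError):
    """A montage or header contains a repeated channel label."""


@dataclass(frozen=True)
class Event:
    """One marker: ``onset`` is a 0-based sample index."""

    type: str
    onset: int
    description: str = ""


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG in microvolts.

    ``samples`` has shape ``(n_channels, n_samples)``.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    reference: str = "nose"
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ChannelCountMismatchError(
                f"{self.samples.shape[0]} sample rows vs "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.samples.shape[1]
        for ev in self.events:
            if not 0 <= ev.onset < n:
                raise ValueError(f"event onset {ev.onset} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.samples.copy(),
            self.sampling_rate,
            list(self.channel_labels),
            self.reference,
            list(self.events),
        )


@dataclass
class ChannelMontage:
    """Channel labels with 3-D positions in millimetres (head frame)."""

    labels: list[str]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise DuplicateLabelError("montage contains duplicate channel labels")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: Sequence[str]) -> "ChannelMontage":
        idx = [self.index(l) for l in labels]
        return ChannelMontage(list(labels), self.positions[idx])


@dataclass
class EpochedRecording:
    """Trials x channels x time, times in ms relative to first-tone onset."""

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x time)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ChannelCountMismatchError("channel axis does not match labels")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match times vector")
        step = 1000.0 / self.sampling_rate
        if self.times.size > 1 and not np.allclose(np.diff(self.times), step):
            raise ValueError("times must increase uniformly at 1000/sampling_rate")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata row count must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_mask(self, window_ms: tuple[float, float]) -> np.ndarray:
        """Boolean mask over the time axis for half-open ``[start, end)``."""
        lo, hi = window_ms
        return (self.times >= lo) & (self.times < hi)

    def select_trials(self, mask: np.ndarray) -> "EpochedRecording":
        mask = np.asarray(mask)
        return EpochedRecording(
            self.data[mask],
            self.times.copy(),
            self.sampling_rate,
            list(self.channel_labels),
            self.metadata.loc[mask].reset_index(drop=True),
        )

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            self.data.copy(),
            self.times.copy(),
            self.sampling_rate,
            list(self.channel_labels),
            self.metadata.copy(),
        )


# ---------------------------------------------------------------------------
# BrainVision read/write
# ---------------------------------------------------------------------------

_HEADER_MAGIC = "Brain Vision Data Exchange Header File"
_MARKER_MAGIC = "Brain Vision Data Exchange Marker File"


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = sections.setdefault(m.group(1), {})
            continue
        if current is not None and "=" in line:
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    return sections


def write_brainvision(
    recording: ContinuousRecording,
    out_prefix: str | Path,
    resolution_uv: float = 0.1,
) -> tuple[Path, Path, Path]:
    """Write a ``.vhdr``/``.eeg``/``.vmrk`` triplet; returns the three paths.

    Data are stored as INT16 multiplexed little-endian with the given
    per-channel resolution in microvolts.
    """
    if not np.all(np.isfinite(recording.samples)):
        raise ValueError("cannot write non-finite samples")
    if resolution_uv <= 0:
        raise ValueError("resolution must be positive")
    scaled = np.round(recording.samples / resolution_uv)
    if np.any(np.abs(scaled) > 32767):
        raise ValueError(
            f"samples exceed the INT16 range at resolution {resolution_uv} uV; "
            "increase the resolution"
        )

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    vhdr = prefix.with_suffix(".vhdr")
    eeg = prefix.with_suffix(".eeg")
    vmrk = prefix.with_suffix(".vmrk")

    ints = scaled.astype("<i2")
    # multiplexed: time-major, channels interleaved
    ints.T.tofile(eeg)

    interval_us = 1_000_000.0 / recording.sampling_rate
    interval = (
        f"{interval_us:.6f}".rstrip("0").rstrip(".")
        if interval_us != int(interval_us)
        else str(int(interval_us))
    )
    lines = [
        f"{_HEADER_MAGIC} Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval}",
        "",
        "[Binary Infos]",
        "BinaryFormat=INT_16",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(recording.channel_labels, start=1):
        lines.append(f"Ch{i}={label},{recording.reference},{resolution_uv},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        f"{_MARKER_MAGIC}, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
    ]
    for i, ev in enumerate(recording.events, start=1):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{i}={ev.type},{ev.description},{ev.onset + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr, eeg, vmrk


def read_brainvision(header_path: str | Path) -> ContinuousRecording:
    """Read a BrainVision triplet written in the supported dialect."""
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise MissingCompanionFileError(f"header not found: {vhdr}")
    text = vhdr.read_text(encoding="utf-8")
    if not text.startswith(_HEADER_MAGIC):
        raise UnsupportedFormatError(f"{vhdr} is not a BrainVision header")
    sections = _parse_ini(text)
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})

    if common.get("DataFormat", "BINARY") != "BINARY":
        raise UnsupportedFormatError(
            f"unsupported DataFormat {common.get('DataFormat')!r}"
        )
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise UnsupportedFormatError(
            f"unsupported DataOrientation {common.get('DataOrientation')!r}"
        )
    if binary.get("BinaryFormat", "INT_16") != "INT_16":
        raise UnsupportedFormatError(
            f"unsupported BinaryFormat {binary.get('BinaryFormat')!r}"
        )

    n_channels = int(common["NumberOfChannels"])
    sampling_rate = 1_000_000.0 / float(common["SamplingInterval"])

    eeg = vhdr.parent / common["DataFile"]
    if not eeg.exists():
        raise MissingCompanionFileError(f"data file not found: {eeg}")

    labels: list[str] = []
    resolutions = np.ones(n_channels)
    reference = "nose"
    chinfo = sections.get("Channel Infos", {})
    for i in range(1, n_channels + 1):
        entry = chinfo.get(f"Ch{i}")
        if entry is None:
            raise UnsupportedFormatError(f"header missing Ch{i} entry")
        parts = entry.split(",")
        labels.append(parts[0])
        if len(parts) > 1 and parts[1]:
            reference = parts[1]
        if len(parts) > 2 and parts[2]:
            resolutions[i - 1] = float(parts[2])
    if len(labels) != len(set(labels)):
        raise DuplicateLabelError("header contains duplicate channel labels")

    raw = np.fromfile(eeg, dtype="<i2")
    if raw.size % n_channels != 0:
        raise ChannelCountMismatchError(
            f"{eeg} holds {raw.size} values, not a multiple of "
            f"{n_channels} channels"
        )
    samples = raw.reshape(-1, n_channels).T.astype(float)
    samples *= resolutions[:, None]

    events: list[Event] = []
    marker_name = common.get("MarkerFile")
    if marker_name:
        vmrk = vhdr.parent / marker_name
        if not vmrk.exists():
            raise MissingCompanionFileError(f"marker file not found: {vmrk}")
        msections = _parse_ini(vmrk.read_text(encoding="utf-8"))
        infos = msections.get("Marker Infos", {})
        for key in sorted(infos, key=lambda k: int(k[2:])):
            parts = infos[key].split(",")
            mtype, desc, position = parts[0], parts[1], int(parts[2])
            events.append(Event(mtype, position - 1, desc))

    return ContinuousRecording(samples, sampling_rate, labels, reference, events)


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

BUILTIN_MONTAGES = {"standard-62": "standard_62.sfp"}


def load_montage(name_or_path: str | Path = "standard-62") -> ChannelMontage:
    """Load a montage by built-in name or from an ``.sfp``-style text file.

    Each line reads ``label x y z`` with coordinates in millimetres.
    """
    name = str(name_or_path)
    if name in BUILTIN_MONTAGES:
        ref = resources.files("thetatrain") / "montages" / BUILTIN_MONTAGES[name]
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(name_or_path).read_text(encoding="utf-8")

    labels: list[str] = []
    coords: list[list[float]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed montage line: {line!r}")
        labels.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    if len(labels) < 2:
        raise ValueError("montage must define at least 2 channels")
    return ChannelMontage(labels, np.asarray(coords))


def save_epochs(path: str | Path, epochs: EpochedRecording) -> Path:
    """Persist epochs as a ``.npz`` container (runtime interchange only)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        data=epochs.data,
        times=epochs.times,
        sampling_rate=epochs.sampling_rate,
        channel_labels=np.array(epochs.channel_labels),
        metadata_json=np.array(epochs.metadata.to_json(orient="table")),
    )
    return path


def load_epochs(path: str | Path) -> EpochedRecording:
    with np.load(path, allow_pickle=False) as z:
        meta = pd.read_json(
            _io.StringIO(str(z["metadata_json"])), orient="table"
        )
        return EpochedRecording(
            z["data"],
            z["times"],
            float(z["sampling_rate"]),
            [str(l) for l in z["channel_labels"]],
            meta,
        )


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(
    recording: ContinuousRecording,
    event_type: str,
    window_ms: tuple[float, float],
    metadata: pd.DataFrame | None = None,
) -> EpochedRecording:
    """Cut trials around events of ``event_type``; window is half-open.

    ``metadata`` rows, when given, are joined positionally with the selected
    events and must have one row per selected event.  Events whose window
    would extend past the recording edge are dropped (and logged), along with
    their metadata rows.
    """
    start_ms, end_ms = window_ms
    if end_ms <= start_ms:
        raise ValueError("window end must exceed start")
    fs = recording.sampling_rate
    offset = int(round(start_ms * fs / 1000.0))
    n_times = int(round((end_ms - start_ms) * fs / 1000.0))

    selected = [ev for ev in recording.events if ev.type == event_type]
    if metadata is not None and len(metadata) != len(selected):
        raise ValueError(
            f"metadata has {len(metadata)} rows for {len(selected)} events"
        )

    kept_rows: list[int] = []
    segments: list[np.ndarray] = []
    for i, ev in enumerate(selected):
        lo = ev.onset + offset
        hi = lo + n_times
        if lo < 0 or hi > recording.n_samples:
            logger.warning(
                "dropping trial %d: window [%d, %d) outside recording of %d samples",
                i, lo, hi, recording.n_samples,
            )
            continue
        kept_rows.append(i)
        segments.append(recording.samples[:, lo:hi])

    data = (
        np.stack(segments)
        if segments
        else np.empty((0, recording.n_channels, n_times))
    )
    times = start_ms + np.arange(n_times) * 1000.0 / fs
    if metadata is not None:
        meta = metadata.iloc[kept_rows].reset_index(drop=True)
    else:
        meta = pd.DataFrame({"trial": kept_rows})
    return EpochedRecording(data, times, fs, list(recording.channel_labels), meta)
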