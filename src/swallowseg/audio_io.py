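"""WAV and annotation I/O, resampling, amplitude normalization.

Audio is represented as a mono float waveform in [-1, 1] plus a sample rate;
swallow annotations are half-open time intervals in seconds, stored on disk
as a three-column CSV (``start_s,end_s,label``).
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .config import SAMPLE_RATE

__all__ = [
    "AudioSignal",
    "EventInterval",
    "EventList",
    "read_wav",
    "write_wav",
    "resample",
    "normalize_amplitude",
    "read_events_csv",
    "write_events_csv",
]


@dataclass(frozen=True)
class AudioSignal:
    """Mono waveform (dimensionless amplitude) with its sample rate in Hz."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"AudioSignal must be mono (1-D); got shape {samples.shape}")
        if self.rate <= 0:
            raise ValueError(f"sample rate must be positive; got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True, order=True)
class EventInterval:
    """Half-open labelled time interval [start_s, end_s) in seconds."""

    start_s: float
    end_s: float
    label: str = "swallow"

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ValueError(f"negative start time {self.start_s}")
        if not self.end_s > self.start_s:
            raise ValueError(f"interval must satisfy start < end; got [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlap_s(self, start_s: float, end_s: float) -> float:
        """Length of the intersection with [start_s, end_s)."""
        return max(0.0, min(self.end_s, end_s) - max(self.start_s, start_s))


@dataclass(frozen=True)
class EventList:
    """Events sorted by start time. Ground-truth lists must be disjoint."""

    events: tuple[EventInterval, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events, key=lambda e: (e.start_s, e.end_s)))
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[EventInterval]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def is_disjoint(self) -> bool:
        return all(a.end_s <= b.start_s for a, b in zip(self.events, self.events[1:]))

    def require_disjoint(self) -> "EventList":
        if not self.is_disjoint():
            raise ValueError("events overlap; expected pairwise-disjoint intervals")
        return self

    def total_duration_s(self) -> float:
        return sum(e.duration_s for e in self.events)

    def union_intervals(self) -> list[tuple[float, float]]:
        """Merged, disjoint (start, end) cover of all events."""
        merged: list[tuple[float, float]] = []
        for e in self.events:
            if merged and e.start_s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e.end_s))
            else:
                merged.append((e.start_s, e.end_s))
        return merged

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]], label: str = "swallow") -> "EventList":
        return cls(tuple(EventInterval(s, e, label) for s, e in pairs))


def read_wav(path: str | os.PathLike) -> AudioSignal:
    """Read a PCM/float WAV as a mono AudioSignal scaled to [-1, 1].

    Multi-channel audio is averaged across channels; integer formats are
    divided by their full-scale value.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"audio file not found: {path}")
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise ValueError(f"could not read WAV file {path}: {exc}") from exc

    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype} in {path}")

    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioSignal(samples=samples, rate=int(rate))


def write_wav(path: str | os.PathLike, signal: AudioSignal) -> None:
    """Write a 16-bit PCM WAV; samples are clipped to [-1, 1] first."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(os.fspath(path), signal.rate, pcm)


def resample(signal: AudioSignal, target_rate: int = SAMPLE_RATE) -> AudioSignal:
    """Band-limited (polyphase) resampling to ``target_rate``.

    Output length is round(N * target_rate / rate). A signal already at the
    target rate is returned unchanged.
    """
    if target_rate <= 0:
        raise ValueError(f"target rate must be positive; got {target_rate}")
    if signal.rate == target_rate:
        return signal
    g = math.gcd(int(signal.rate), int(target_rate))
    up, down = int(target_rate) // g, int(signal.rate) // g
    out = resample_poly(signal.samples, up, down)
    n_expected = int(round(len(signal.samples) * target_rate / signal.rate))
    if len(out) > n_expected:
        out = out[:n_expected]
    elif len(out) < n_expected:
        out = np.pad(out, (0, n_expected - len(out)))
    return AudioSignal(samples=out, rate=target_rate)


def normalize_amplitude(signal: AudioSignal) -> AudioSignal:
    """Scale so max |sample| is exactly 1; all-zero input is returned as-is."""
    peak = float(np.max(np.abs(signal.samples))) if len(signal) else 0.0
    if peak == 0.0:
        return signal
    return replace(signal, samples=signal.samples / peak)


_CSV_HEADER = ["start_s", "end_s", "label"]


def read_events_csv(path: str | os.PathLike) -> EventList:
    """Read an annotation CSV (header ``start_s,end_s,label``), sorted on load.

    Malformed rows raise with the offending line number.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"annotation file not found: {path}")
    events: list[EventInterval] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != _CSV_HEADER:
            raise ValueError(f"{path}: expected header 'start_s,end_s,label', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            try:
                start, end = float(row[0]), float(row[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric time in {row[:2]}") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start time {start}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} must exceed start {start}")
            events.append(EventInterval(start, end, row[2].strip()))
    return EventList(tuple(events))


def write_events_csv(events: EventList, path: str | os.PathLike) -> None:
    """Write events at millisecond precision; read_events_csv round-trips."""
    with open(os.fspath(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for e in events:
            writer.writerow([f"{e.start_s:.3f}", f"{e.end_s:.3f}", e.label])
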