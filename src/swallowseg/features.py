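"""Framing and per-frame acoustic features: log-mel patch and zero-crossing rate.

A recording at 16 kHz is cut into 0.96 s frames with 50 % overlap (hop
0.48 s); the final partial frame is zero-padded so tail-of-recording events
remain visible. Each frame is summarised as a 96 x 64 log-mel patch (25 ms
Hann window, 10 ms hop, 64 triangular mel bands over 125-7500 Hz,
log(energy + 0.001)) and a scalar zero-crossing rate in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import get_window

from . import config
from .audio_io import AudioSignal

__all__ = [
    "FrameSet",
    "FrameFeatures",
    "frame_signal",
    "log_mel",
    "zcr",
    "mel_filterbank",
    "frame_features",
]


@dataclass(frozen=True)
class FrameSet:
    """Overlapping fixed-length frames of one recording.

    ``frames`` has shape (n_frames, FRAME_SAMPLES); ``frame_starts`` holds each
    frame's start time in seconds (multiples of the 0.48 s hop).
    """

    frames: np.ndarray
    frame_starts: np.ndarray
    rate: int = config.SAMPLE_RATE

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class FrameFeatures:
    """Per-frame feature bundle: log-mel patch, ZCR scalar, start time."""

    logmel: np.ndarray
    zcr: float
    frame_start_s: float


def frame_signal(
    signal: AudioSignal,
    frame_s: float = config.FRAME_S,
    overlap: float = 0.5,
) -> FrameSet:
    """Slice a 16 kHz recording into overlapping frames.

    Frame count is ``1 + ceil(max(N - frame, 0) / hop)``; the last frame is
    zero-padded to full length so every sample is covered.
    """
    if signal.rate != config.SAMPLE_RATE:
        raise ValueError(
            f"frame_signal expects {config.SAMPLE_RATE} Hz audio; got {signal.rate} Hz "
            "-- resample the signal first"
        )
    if len(signal) == 0:
        raise ValueError("cannot frame an empty signal")
    frame_n = int(round(frame_s * signal.rate))
    hop_n = int(round(frame_n * (1.0 - overlap)))
    n = len(signal.samples)
    n_frames = 1 + math.ceil(max(n - frame_n, 0) / hop_n)

    padded = np.zeros((n_frames - 1) * hop_n + frame_n, dtype=np.float64)
    padded[:n] = signal.samples
    idx = np.arange(frame_n)[None, :] + hop_n * np.arange(n_frames)[:, None]
    frames = padded[idx]
    starts = hop_n * np.arange(n_frames) / signal.rate
    return FrameSet(frames=frames, frame_starts=starts, rate=signal.rate)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


@lru_cache(maxsize=4)
def mel_filterbank(
    n_mels: int = config.N_MELS,
    n_fft: int = config.N_FFT,
    rate: int = config.SAMPLE_RATE,
    fmin: float = config.MEL_FMIN,
    fmax: float = config.MEL_FMAX,
) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1).

    Band k has support between edge frequencies k and k+2 of n_mels + 2
    points equally spaced on the HTK mel scale between fmin and fmax.
    """
    edges_hz = _mel_to_hz(np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2))
    bin_hz = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, len(bin_hz)))
    for k in range(n_mels):
        lo, mid, hi = edges_hz[k], edges_hz[k + 1], edges_hz[k + 2]
        up = (bin_hz - lo) / (mid - lo)
        down = (hi - bin_hz) / (hi - mid)
        fb[k] = np.maximum(0.0, np.minimum(up, down))
    return fb


def band_edges_hz(n_mels: int = config.N_MELS) -> np.ndarray:
    """The n_mels + 2 mel-spaced edge frequencies (Hz) of the filterbank."""
    return _mel_to_hz(
        np.linspace(_hz_to_mel(config.MEL_FMIN), _hz_to_mel(config.MEL_FMAX), n_mels + 2)
    )


def log_mel(frame_samples: np.ndarray) -> np.ndarray:
    """Log-mel patch of one analysis frame; shape (96, 64).

    Magnitude STFT (25 ms Hann, 10 ms hop, 512-point FFT) mapped through the
    mel filterbank, then log(x + 0.001). The frame tail is zero-padded so
    exactly 96 STFT steps result; an all-zero frame yields the constant
    log(0.001).
    """
    x = np.asarray(frame_samples, dtype=np.float64)
    if x.shape != (config.FRAME_SAMPLES,):
        raise ValueError(
            f"log_mel expects exactly {config.FRAME_SAMPLES} samples; got shape {x.shape}"
        )
    win_n = int(round(config.STFT_WINDOW_S * config.SAMPLE_RATE))
    hop_n = int(round(config.STFT_HOP_S * config.SAMPLE_RATE))
    n_steps = config.N_PATCH_STEPS
    needed = (n_steps - 1) * hop_n + win_n
    if needed > len(x):
        x = np.pad(x, (0, needed - len(x)))
    windows = np.lib.stride_tricks.sliding_window_view(x, win_n)[::hop_n][:n_steps]
    window = get_window("hann", win_n, fftbins=True)
    spec = np.abs(np.fft.rfft(windows * window, n=config.N_FFT, axis=1))
    mel = spec @ mel_filterbank().T
    return np.log(mel + config.LOG_OFFSET)


def zcr(frame_samples: np.ndarray) -> float:
    """Zero-crossing rate: sign changes / (L - 1), zeros counted as positive."""
    x = np.asarray(frame_samples, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("zcr needs a 1-D frame with at least 2 samples")
    signs = np.where(x >= 0.0, 1, -1)
    return float(np.count_nonzero(signs[1:] != signs[:-1])) / (len(x) - 1)


def frame_features(signal: AudioSignal) -> list[FrameFeatures]:
    """Convenience: frame a 16 kHz recording and compute per-frame features."""
    frames = frame_signal(signal)
    return [
        FrameFeatures(logmel=log_mel(frames.frames[i]), zcr=zcr(frames.frames[i]),
                      frame_start_s=float(frames.frame_starts[i]))
        for i in range(len(frames))
    ]
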