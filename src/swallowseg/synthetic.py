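"""Synthetic cervical-auscultation recordings with gold swallow annotations.

Each synthetic participant is a one-minute mono 16 kHz recording: a colored
noise background (pink by default), 5-20 swallow events of 0.3-0.9 s (each a
train of 2-3 band-limited 300-3000 Hz noise bursts with exponential-decay
envelopes, calibrated so the mean in-band power inside the event sits
``snr_db`` above the background), plus distractor sounds — low-frequency
tonal hums (200-500 Hz) and single loud broadband clicks — that never
overlap swallows and are absent from the annotations. Everything is
deterministic per seed.

The acoustic surrogate claims separability, not clinical realism: it gives
the pipeline a controllable, labelled stand-in for recordings that cannot
be shared.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .audio_io import AudioSignal, EventList, write_events_csv, write_wav

__all__ = ["SimConfig", "generate_recording", "generate_cohort"]

_SWALLOW_BAND_HZ = (300.0, 3000.0)
_EDGE_MARGIN_S = 0.25          # keep events away from recording boundaries
_BACKGROUND_RMS = 0.05         # reference background level (full scale = 1)
_NOISE_EXPONENTS = {"white": 0.0, "pink": 1.0, "brown": 2.0}


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one synthetic recording.

    ``n_events=None`` draws 5-20 events per recording; ``background_gain_db``
    shifts the background level (used for train/test domain mismatch).
    """

    duration_s: float = 60.0
    n_events: int | None = None
    event_duration_range_s: tuple[float, float] = (0.3, 0.9)
    min_gap_s: float = 0.5
    snr_db: float = 10.0
    distractor_rate_per_min: float = 4.0
    background: str = "pink"
    background_gain_db: float = 0.0
    sample_rate: int = 16_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        lo, hi = self.event_duration_range_s
        if not 0 < lo <= hi:
            raise ValueError(f"invalid event duration range {self.event_duration_range_s}")
        if self.background not in _NOISE_EXPONENTS:
            raise ValueError(f"unknown background {self.background!r}; choose from {sorted(_NOISE_EXPONENTS)}")


_NOISE_HP_HZ = 20.0  # AC-coupling cutoff: no infrasonic drift below this


def _colored_noise(rng: np.random.Generator, n: int, exponent: float, rate: int) -> np.ndarray:
    """Unit-RMS noise with power spectral density ~ 1/f^exponent.

    The 1/f shaping is floored at _NOISE_HP_HZ so steep spectra (brown)
    do not produce unbounded infrasonic drift; recording chains are
    AC-coupled and carry no such wander.
    """
    spectrum = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.zeros_like(f)
    scale[1:] = np.maximum(f[1:], _NOISE_HP_HZ) ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n)
    return x / np.sqrt(np.mean(x**2))


def _band_sos(rate: int):
    return butter(4, _SWALLOW_BAND_HZ, btype="bandpass", fs=rate, output="sos")


def _place_events(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[float, float]]:
    """Disjoint event intervals honoring gaps and edge margins."""
    n = cfg.n_events if cfg.n_events is not None else int(rng.integers(5, 21))
    if n == 0:
        return []
    lo, hi = cfg.event_duration_range_s
    durations = rng.uniform(lo, hi, n)
    occupied = durations.sum() + (n - 1) * cfg.min_gap_s + 2 * _EDGE_MARGIN_S
    slack = cfg.duration_s - occupied
    if slack < 0:
        raise ValueError(
            f"cannot pack {n} events of up to {hi} s with {cfg.min_gap_s} s gaps into "
            f"{cfg.duration_s} s; reduce n_events or durations"
        )
    offsets = np.sort(rng.uniform(0.0, slack, n))
    events = []
    cursor = _EDGE_MARGIN_S
    for i in range(n):
        start = cursor + offsets[i]
        events.append((start, start + durations[i]))
        cursor = start + durations[i] + cfg.min_gap_s - offsets[i]
    return events


def _swallow_snippet(rng: np.random.Generator, n: int, rate: int, sos) -> np.ndarray:
    """2-3 decaying band-limited bursts spanning an event of n samples.

    Burst onsets are spread across the whole interval (one per k-th of it,
    jittered) so the event is audible throughout its annotated extent — the
    annotation convention being emulated marks the end of the audible sound.
    """
    snippet = np.zeros(n)
    n_bursts = int(rng.integers(2, 4))
    onset_fracs = (np.arange(n_bursts) + rng.uniform(0.0, 0.6, n_bursts)) / n_bursts
    for frac in onset_fracs:
        t0 = int(frac * n)
        tail = n - t0
        tau_s = rng.uniform(0.08, 0.15)
        env = np.exp(-np.arange(tail) / (tau_s * rate))
        burst = sosfiltfilt(sos, rng.standard_normal(tail + 200))[100:-100]
        snippet[t0:] += rng.uniform(0.6, 1.0) * env * burst
    return snippet


def _overlaps_any(start: float, end: float, intervals, margin: float = 0.1) -> bool:
    return any(start < e + margin and end > s - margin for s, e in intervals)


def generate_recording(config: SimConfig) -> tuple[AudioSignal, EventList]:
    """One synthetic recording plus its gold swallow annotations."""
    rng = np.random.default_rng(config.seed)
    rate = config.sample_rate
    n = int(round(config.duration_s * rate))
    sos = _band_sos(rate)

    bg_rms = _BACKGROUND_RMS * 10.0 ** (config.background_gain_db / 20.0)
    signal = bg_rms * _colored_noise(rng, n, _NOISE_EXPONENTS[config.background], rate)
    bg_band_power = float(np.mean(sosfiltfilt(sos, signal) ** 2))

    events = _place_events(rng, config)
    target_power = bg_band_power * 10.0 ** (config.snr_db / 10.0)
    for start, end in events:
        i0, i1 = int(round(start * rate)), int(round(end * rate))
        snippet = _swallow_snippet(rng, i1 - i0, rate, sos)
        power = float(np.mean(snippet**2))
        if power > 0:
            signal[i0:i1] += snippet * np.sqrt(target_power / power)

    # distractors: tonal hums and single loud clicks, never on swallows
    minutes = config.duration_s / 60.0
    n_hums = rng.poisson(config.distractor_rate_per_min * minutes / 2.0)
    n_clicks = rng.poisson(config.distractor_rate_per_min * minutes / 2.0)
    for _ in range(n_hums):
        dur = float(rng.uniform(1.0, 3.0))
        for _try in range(100):
            start = float(rng.uniform(0.0, config.duration_s - dur))
            if not _overlaps_any(start, start + dur, events):
                break
        else:
            continue
        i0, i1 = int(start * rate), int((start + dur) * rate)
        t = np.arange(i1 - i0) / rate
        f0 = float(rng.uniform(200.0, 500.0))
        hum = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        hum *= 1.0 + 0.3 * np.sin(2 * np.pi * 3.0 * t)
        fade = min(800, (i1 - i0) // 4)
        ramp = np.linspace(0.0, 1.0, fade)
        hum[:fade] *= ramp
        hum[-fade:] *= ramp[::-1]
        signal[i0:i1] += 0.5 * bg_rms * np.sqrt(2.0) * hum
    for _ in range(n_clicks):
        dur = float(rng.uniform(0.005, 0.02))
        for _try in range(100):
            start = float(rng.uniform(0.0, config.duration_s - dur))
            if not _overlaps_any(start, start + dur, events):
                break
        else:
            continue
        i0 = int(start * rate)
        m = min(max(int(dur * rate), 8), n - i0)
        env = np.exp(-np.arange(m) / (0.002 * rate))
        signal[i0 : i0 + m] += 10.0 * bg_rms * env * rng.standard_normal(m)

    peak = float(np.max(np.abs(signal)))
    if peak > 0.99:
        signal *= 0.99 / peak

    return AudioSignal(samples=signal, rate=rate), EventList.from_pairs(events)


def generate_cohort(
    out_dir: str | os.PathLike,
    n_train_participants: int,
    n_test_participants: int,
    seed: int = 0,
    config: SimConfig | None = None,
    test_background: str | None = "brown",
    test_background_gain_db: float = 3.0,
) -> dict:
    """Write one WAV + events CSV per synthetic participant, plus a manifest.

    The test cohort can be generated with a shifted background profile
    (different noise color and level) to emulate a train/test domain
    mismatch; pass ``test_background=None`` for a matched test cohort.
    Returns the manifest (also written as ``manifest.json``).
    """
    if n_train_participants < 1 or n_test_participants < 1:
        raise ValueError("cohort needs at least 1 train and 1 test participant")
    out_dir = os.fspath(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir):
        raise FileExistsError(f"refusing to write cohort into non-empty directory {out_dir}")
    os.makedirs(out_dir, exist_ok=True)

    base = config if config is not None else SimConfig()
    seeds = np.random.SeedSequence(seed).generate_state(
        n_train_participants + n_test_participants
    ) & 0x7FFFFFFF

    participants = []
    for i in range(n_train_participants + n_test_participants):
        role = "train" if i < n_train_participants else "test"
        pid = f"{role}{i + 1:02d}" if role == "train" else f"test{i - n_train_participants + 1:02d}"
        cfg = replace(base, seed=int(seeds[i]))
        if role == "test" and test_background is not None:
            cfg = replace(
                cfg,
                background=test_background,
                background_gain_db=base.background_gain_db + test_background_gain_db,
            )
        audio, events = generate_recording(cfg)
        wav_path = os.path.join(out_dir, f"{pid}.wav")
        csv_path = os.path.join(out_dir, f"{pid}.csv")
        write_wav(wav_path, audio)
        write_events_csv(events, csv_path)
        participants.append(
            {
                "id": pid,
                "role": role,
                "wav": f"{pid}.wav",
                "events": f"{pid}.csv",
                "seed": int(seeds[i]),
                "n_events": len(events),
                "background": cfg.background,
                "background_gain_db": cfg.background_gain_db,
            }
        )

    base_dict = asdict(base)
    base_dict["event_duration_range_s"] = list(base.event_duration_range_s)
    manifest = {
        "seed": seed,
        "config": base_dict,
        "test_background": test_background,
        "test_background_gain_db": test_background_gain_db if test_background else 0.0,
        "participants": participants,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
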