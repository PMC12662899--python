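"""Overlap-add decoding of per-frame subframe confidences into events.

Each frame contributes its six 0.16 s subframe confidences to a shared
per-slot timeline; with 50 % frame overlap, interior slots are covered by
two frames. The timeline is coverage-normalized (mean, not raw sum) before
thresholding so a single threshold is meaningful both at recording edges
(coverage 1) and in the interior (coverage 2). Maximal runs of above-
threshold slots become predicted events with boundaries quantized to 0.16 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .audio_io import EventInterval, EventList

__all__ = [
    "ConfidenceTimeline",
    "accumulate",
    "threshold_mask",
    "mask_to_events",
    "decode_events",
]

_GRID_TOL = 1e-6


@dataclass(frozen=True)
class ConfidenceTimeline:
    """Per-0.16 s-slot summed confidence and frame coverage counts."""

    sums: np.ndarray
    coverage: np.ndarray
    slot_s: float = config.SUBFRAME_S

    def __len__(self) -> int:
        return len(self.sums)

    def mean(self) -> np.ndarray:
        """Coverage-normalized confidence per slot (0 where uncovered)."""
        out = np.zeros_like(self.sums)
        covered = self.coverage > 0
        out[covered] = self.sums[covered] / self.coverage[covered]
        return out


def accumulate(
    frame_starts: np.ndarray,
    confidences: np.ndarray,
    slot_s: float = config.SUBFRAME_S,
) -> ConfidenceTimeline:
    """Overlap-add frame confidences onto the global 0.16 s slot grid.

    Frame starts must be multiples of the slot duration (the 0.48 s hop grid
    satisfies this); frame subframe i lands in slot start/0.16 + i.
    """
    frame_starts = np.asarray(frame_starts, dtype=np.float64)
    confidences = np.asarray(confidences, dtype=np.float64)
    if confidences.ndim != 2 or confidences.shape[1] != config.N_SUBFRAMES:
        raise ValueError(f"confidences must have shape (n_frames, 6); got {confidences.shape}")
    if len(frame_starts) != len(confidences):
        raise ValueError("one confidence vector per frame start is required")

    ratio = frame_starts / slot_s
    base_slots = np.round(ratio).astype(int)
    if np.any(np.abs(ratio - base_slots) > _GRID_TOL):
        bad = frame_starts[np.abs(ratio - base_slots) > _GRID_TOL][0]
        raise ValueError(f"frame start {bad} s is not a multiple of the {slot_s} s slot")

    n_slots = int(base_slots.max()) + config.N_SUBFRAMES if len(base_slots) else 0
    sums = np.zeros(n_slots)
    coverage = np.zeros(n_slots, dtype=int)
    for base, conf in zip(base_slots, confidences):
        sums[base : base + config.N_SUBFRAMES] += conf
        coverage[base : base + config.N_SUBFRAMES] += 1
    return ConfidenceTimeline(sums=sums, coverage=coverage, slot_s=slot_s)


def threshold_mask(timeline: ConfidenceTimeline, tau: float = config.DECODER_TAU) -> np.ndarray:
    """Binary slot mask: 1 where mean confidence >= tau (ties go to 1)."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie strictly in (0, 1); got {tau}")
    return (timeline.mean() >= tau).astype(np.int8)


def mask_to_events(
    mask: np.ndarray,
    slot_s: float = config.SUBFRAME_S,
    min_duration_s: float = 0.0,
    merge_gap_s: float = 0.0,
    label: str = "swallow",
) -> EventList:
    """Convert a binary slot mask into predicted events.

    Maximal runs of 1s become [first_slot * slot_s, (last_slot + 1) * slot_s);
    runs separated by gaps <= merge_gap_s are merged, then events shorter
    than min_duration_s are dropped. All boundaries are slot multiples.
    """
    mask = np.asarray(mask).astype(bool)
    runs: list[list[int]] = []  # [first_slot, last_slot]
    for j in np.flatnonzero(mask):
        if runs and j == runs[-1][1] + 1:
            runs[-1][1] = j
        else:
            runs.append([j, j])

    merged: list[list[int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * slot_s <= merge_gap_s + 1e-9:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    events = [
        EventInterval(first * slot_s, (last + 1) * slot_s, label)
        for first, last in merged
        if (last + 1 - first) * slot_s >= min_duration_s - 1e-9
    ]
    return EventList(tuple(events))


def decode_events(
    frame_starts: np.ndarray,
    confidences: np.ndarray,
    tau: float = config.DECODER_TAU,
    min_duration_s: float = 0.0,
    merge_gap_s: float = 0.0,
) -> EventList:
    """accumulate -> threshold -> mask_to_events in one call."""
    timeline = accumulate(frame_starts, confidences)
    mask = threshold_mask(timeline, tau)
    return mask_to_events(mask, timeline.slot_s, min_duration_s, merge_gap_s)
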