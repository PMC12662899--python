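"""Ground-truth subframe labels.

Each 0.96 s frame is subdivided into six 0.16 s subframes; subframe i of a
frame starting at t covers [t + 0.16 i, t + 0.16 (i+1)). A subframe is
labelled 1 when the swallow intervals cover at least half of it (0.08 s) —
a symmetric rule that suppresses sliver labels and bounds the boundary error
at 0.08 s per edge. Labels depend only on absolute time, so overlapping
frames always agree on shared slots.
"""

from __future__ import annotations

import numpy as np

from . import config
from .audio_io import EventList
from .features import FrameSet

__all__ = ["subframe_labels", "labels_for_recording"]

_EPS = 1e-9


def subframe_labels(frame_start_s: float, events: EventList) -> np.ndarray:
    """Six binary labels for the frame starting at ``frame_start_s``.

    Subframe i is 1 iff the union of event intervals overlaps
    [t + 0.16 i, t + 0.16 (i+1)) by at least 0.08 s.
    """
    labels = np.zeros(config.N_SUBFRAMES, dtype=np.int8)
    union = events.union_intervals()
    for i in range(config.N_SUBFRAMES):
        lo = frame_start_s + i * config.SUBFRAME_S
        hi = lo + config.SUBFRAME_S
        overlap = sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in union)
        if overlap >= config.LABEL_MIN_OVERLAP_S - _EPS:
            labels[i] = 1
    return labels


def labels_for_recording(frames: FrameSet, events: EventList) -> np.ndarray:
    """Stack of subframe labels, one row per frame; shape (n_frames, 6)."""
    return np.stack([subframe_labels(float(t), events) for t in frames.frame_starts])
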