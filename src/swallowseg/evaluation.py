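"""Event- and subframe-level scoring of predicted swallows.

Event level: a ground-truth swallow counts as a true positive when at least
30 % of its duration is covered by the union of predicted swallow time
(fragmented predictions may jointly reach the threshold); otherwise it is a
false negative. A predicted event is a true positive if it touches any
detected (TP) truth event, else a false positive.

Subframe level: binary masks on the common 0.16 s grid are tallied slot-wise
into a confusion matrix, from which the clinical metric suite (PPV, NPV,
specificity, sensitivity, F1 per class, overall accuracy) is computed.
Undefined ratios (zero denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import config
from .audio_io import EventList

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "MetricsReport",
    "EventMatchResult",
    "match_events",
    "events_to_mask",
    "subframe_confusion",
    "metrics_from_counts",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with class 1 = swallow as "positive"."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    ppv: float
    npv: float
    specificity: float
    sensitivity: float
    f1: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("ppv", "npv", "specificity", "sensitivity", "f1")}


@dataclass(frozen=True)
class MetricsReport:
    """Per-class metric suite plus overall accuracy.

    By construction sensitivity(non-swallow) = specificity(swallow),
    ppv(non-swallow) = npv(swallow), and vice versa.
    """

    swallow: ClassMetrics
    non_swallow: ClassMetrics
    accuracy: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "swallow": self.swallow.to_dict(),
            "non_swallow": self.non_swallow.to_dict(),
            "counts": {
                "tp": self.counts.tp,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
                "tn": self.counts.tn,
            },
        }


@dataclass(frozen=True)
class EventMatchResult:
    """Per-event verdicts and aggregate event-level counts."""

    truth_verdicts: tuple[str, ...]      # "TP" or "FN" per truth event
    predicted_verdicts: tuple[str, ...]  # "TP" or "FP" per predicted event
    tp: int
    fn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def precision(self) -> float:
        n_pred_tp = self.predicted_verdicts.count("TP")
        n_pred = len(self.predicted_verdicts)
        return n_pred_tp / n_pred if n_pred else math.nan


def match_events(
    truth: EventList,
    predicted: EventList,
    min_overlap_frac: float = config.EVENT_MIN_OVERLAP_FRAC,
) -> EventMatchResult:
    """Score predicted events against disjoint ground truth.

    A truth event is TP iff the union of predictions covers at least
    ``min_overlap_frac`` of its duration (inclusive). A predicted event is
    TP iff it intersects some TP truth event.
    """
    truth.require_disjoint()
    pred_union = predicted.union_intervals()

    truth_verdicts = []
    for t in truth:
        covered = sum(max(0.0, min(e, t.end_s) - max(s, t.start_s)) for s, e in pred_union)
        frac = covered / t.duration_s
        truth_verdicts.append("TP" if frac >= min_overlap_frac - 1e-12 else "FN")

    tp_truth = [t for t, v in zip(truth, truth_verdicts) if v == "TP"]
    predicted_verdicts = []
    for p in predicted:
        hits = any(p.overlap_s(t.start_s, t.end_s) > 0 for t in tp_truth)
        predicted_verdicts.append("TP" if hits else "FP")

    return EventMatchResult(
        truth_verdicts=tuple(truth_verdicts),
        predicted_verdicts=tuple(predicted_verdicts),
        tp=truth_verdicts.count("TP"),
        fn=truth_verdicts.count("FN"),
        fp=predicted_verdicts.count("FP"),
    )


def events_to_mask(
    events: EventList, n_slots: int, slot_s: float = config.SUBFRAME_S
) -> np.ndarray:
    """Binary slot mask: slot j is 1 when events cover at least half of it."""
    mask = np.zeros(n_slots, dtype=np.int8)
    union = events.union_intervals()
    for j in range(n_slots):
        lo, hi = j * slot_s, (j + 1) * slot_s
        overlap = sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in union)
        if overlap >= slot_s / 2 - 1e-9:
            mask[j] = 1
    return mask


def subframe_confusion(true_mask: np.ndarray, predicted_mask: np.ndarray) -> ConfusionCounts:
    """Slot-wise confusion tally of two equal-length binary masks."""
    t = np.asarray(true_mask).astype(bool)
    p = np.asarray(predicted_mask).astype(bool)
    if t.shape != p.shape:
        raise ValueError(f"mask length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(t & p)),
        fp=int(np.count_nonzero(~t & p)),
        fn=int(np.count_nonzero(t & ~p)),
        tn=int(np.count_nonzero(~t & ~p)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def _f1(ppv: float, sens: float) -> float:
    if math.isnan(ppv) or math.isnan(sens) or ppv + sens == 0:
        return math.nan
    return 2.0 * ppv * sens / (ppv + sens)


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Table of PPV/NPV/specificity/sensitivity/F1 per class plus accuracy."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn

    sw_ppv = _ratio(tp, tp + fp)
    sw_npv = _ratio(tn, tn + fn)
    sw_sens = _ratio(tp, tp + fn)
    sw_spec = _ratio(tn, tn + fp)
    swallow = ClassMetrics(sw_ppv, sw_npv, sw_spec, sw_sens, _f1(sw_ppv, sw_sens))
    # the non-swallow class swaps the roles of positives and negatives
    non_swallow = ClassMetrics(sw_npv, sw_ppv, sw_sens, sw_spec, _f1(sw_npv, sw_spec))
    return MetricsReport(
        swallow=swallow,
        non_swallow=non_swallow,
        accuracy=(tp + tn) / counts.total,
        counts=counts,
    )
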