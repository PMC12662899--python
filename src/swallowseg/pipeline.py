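"""End-to-end wiring: recordings -> features -> head -> events -> scores.

These helpers connect the module-level operations into the flows the CLI
and the reproduction script run: building a labelled dataset from a cohort
directory, training the head with a participant-wise 80/20 split, segmenting
a recording into predicted swallow events, and scoring a test cohort with
the 30 % event-overlap rule.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import config
from .audio_io import (
    AudioSignal,
    EventList,
    normalize_amplitude,
    read_events_csv,
    read_wav,
    resample,
)
from .decoder import decode_events
from .embedding import EmbeddingBackend, embed, concat_features
from .evaluation import match_events
from .features import frame_signal, log_mel, zcr
from .labeling import labels_for_recording
from .model import HeadConfig, LabelledDataset, TrainedHead, split_by_participant, train

__all__ = [
    "prepare_signal",
    "extract_features",
    "dataset_from_recording",
    "dataset_from_cohort",
    "train_on_cohort",
    "segment_signal",
    "evaluate_cohort",
    "run_synthetic_experiment",
]


def prepare_signal(signal: AudioSignal) -> AudioSignal:
    """Resample to 16 kHz and normalize amplitude (the standard front door)."""
    return normalize_amplitude(resample(signal, config.SAMPLE_RATE))


def extract_features(
    signal: AudioSignal, backend: EmbeddingBackend
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (embedding ++ zcr) matrix and frame start times.

    ``signal`` must already be prepared (16 kHz, normalized).
    """
    frames = frame_signal(signal)
    rows = []
    for i in range(len(frames)):
        samples = frames.frames[i]
        frame_zcr = zcr(samples)
        if backend.input_kind == "waveform":
            vec = embed(backend, samples)
        else:
            vec = embed(backend, log_mel(samples))
        rows.append(concat_features(vec, frame_zcr))
    return np.stack(rows), frames.frame_starts


def dataset_from_recording(
    participant: str, signal: AudioSignal, events: EventList, backend: EmbeddingBackend
) -> LabelledDataset:
    """Labelled per-frame examples for one participant's recording."""
    prepared = prepare_signal(signal)
    features, _starts = extract_features(prepared, backend)
    labels = labels_for_recording(frame_signal(prepared), events)
    return LabelledDataset(
        participants=np.array([participant] * len(features), dtype=object),
        features=features,
        labels=labels,
    )


def _load_manifest(cohort_dir: str | os.PathLike) -> dict:
    path = os.path.join(os.fspath(cohort_dir), "manifest.json")
    if not os.path.exists(path):
        raise FileNotFoundError(f"no manifest.json in cohort directory {cohort_dir}")
    with open(path) as fh:
        return json.load(fh)


def dataset_from_cohort(
    cohort_dir: str | os.PathLike, role: str, backend: EmbeddingBackend
) -> LabelledDataset:
    """Labelled dataset over all manifest participants with the given role."""
    cohort_dir = os.fspath(cohort_dir)
    manifest = _load_manifest(cohort_dir)
    parts = [p for p in manifest["participants"] if p["role"] == role]
    if not parts:
        raise ValueError(f"cohort {cohort_dir} has no participants with role {role!r}")
    datasets = []
    for p in parts:
        signal = read_wav(os.path.join(cohort_dir, p["wav"]))
        events = read_events_csv(os.path.join(cohort_dir, p["events"]))
        datasets.append(dataset_from_recording(p["id"], signal, events, backend))
    return LabelledDataset.concatenate(datasets)


def train_on_cohort(
    cohort_dir: str | os.PathLike,
    backend: EmbeddingBackend,
    seed: int = 0,
    train_fraction: float = 0.8,
    head_config: HeadConfig | None = None,
) -> TrainedHead:
    """Train the head on a cohort's train-role recordings (80/20 by participant)."""
    if head_config is None:
        head_config = HeadConfig(input_dim=backend.dim + 1, seed=seed)
    dataset = dataset_from_cohort(cohort_dir, "train", backend)
    train_ds, val_ds = split_by_participant(dataset, train_fraction, seed)
    return train(head_config, train_ds, val_ds, backend)


def segment_signal(
    head: TrainedHead,
    signal: AudioSignal,
    backend: EmbeddingBackend,
    tau: float = config.DECODER_TAU,
    min_duration_s: float = 0.0,
    merge_gap_s: float = 0.0,
) -> EventList:
    """Predict swallow events for one recording."""
    head.check_backend(backend)
    prepared = prepare_signal(signal)
    features, starts = extract_features(prepared, backend)
    confidences = head.predict(features)
    return decode_events(starts, confidences, tau, min_duration_s, merge_gap_s)


def evaluate_cohort(
    head: TrainedHead,
    cohort_dir: str | os.PathLike,
    backend: EmbeddingBackend,
    role: str = "test",
    tau: float = config.DECODER_TAU,
    min_overlap_frac: float = config.EVENT_MIN_OVERLAP_FRAC,
) -> dict:
    """Segment every recording with the given role and aggregate event scores."""
    cohort_dir = os.fspath(cohort_dir)
    manifest = _load_manifest(cohort_dir)
    tp = fn = fp = n_pred_tp = n_pred = 0
    for p in manifest["participants"]:
        if p["role"] != role:
            continue
        signal = read_wav(os.path.join(cohort_dir, p["wav"]))
        truth = read_events_csv(os.path.join(cohort_dir, p["events"]))
        predicted = segment_signal(head, signal, backend, tau)
        result = match_events(truth, predicted, min_overlap_frac)
        tp += result.tp
        fn += result.fn
        fp += result.fp
        n_pred_tp += result.predicted_verdicts.count("TP")
        n_pred += len(result.predicted_verdicts)
    return {
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "n_truth": tp + fn,
        "n_predicted": n_pred,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "precision": n_pred_tp / n_pred if n_pred else float("nan"),
    }


def run_synthetic_experiment(
    workdir: str | os.PathLike,
    seed: int,
    backend: EmbeddingBackend,
    n_train_participants: int = 10,
    n_test_participants: int = 4,
    snr_db: float = 10.0,
    max_epochs: int = 100,
) -> dict:
    """Simulate -> train -> segment -> evaluate, on matched and shifted test cohorts.

    Generates a cohort of ``n_train_participants`` train recordings (split
    80/20 by participant into train/validation) plus ``n_test_participants``
    test recordings in two variants — a matched background and a shifted
    (different noise color, +3 dB) background — trains one head, and scores
    the test cohorts at the 30 % event-overlap rule.
    """
    from .synthetic import SimConfig, generate_cohort

    workdir = os.fspath(workdir)
    base = SimConfig(snr_db=snr_db)
    matched_dir = os.path.join(workdir, "matched")
    shifted_dir = os.path.join(workdir, "shifted")
    generate_cohort(
        matched_dir, n_train_participants, n_test_participants, seed, base,
        test_background=None,
    )
    generate_cohort(
        shifted_dir, n_train_participants, n_test_participants, seed, base,
        test_background="brown", test_background_gain_db=3.0,
    )

    head_config = HeadConfig(input_dim=backend.dim + 1, max_epochs=max_epochs, seed=seed)
    head = train_on_cohort(matched_dir, backend, seed=seed, head_config=head_config)

    return {
        "seed": seed,
        "matched": evaluate_cohort(head, matched_dir, backend),
        "shifted": evaluate_cohort(head, shifted_dir, backend),
        "best_epoch": head.history.get("best_epoch"),
        "epochs_run": len(head.history.get("val_loss", [])),
    }
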