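"""The fully-connected prediction head and its training loop.

Architecture: input (embedding dim + 1) -> 1024 -> 1024 -> 512 -> 6, ReLU in
the hidden layers and sigmoid at the output, so each of the six subframe
confidences lies in (0, 1). Training minimizes mean squared error against
the binary subframe labels with the Adam optimizer, mini-batches of 32, an
L2 penalty on the first two hidden layers' weights, and at most 100 epochs.
Before every epoch the training set is re-balanced (random undersampling of
the majority group between frames containing a swallow subframe and frames
containing none) and shuffled. The epoch with the lowest validation loss is
kept; early stopping aborts after a patience of non-improving epochs.

Datasets are split by participant, never by example, so no participant can
appear on both sides of the train/validation divide.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .embedding import EmbeddingBackend

__all__ = [
    "HeadConfig",
    "LabelledDataset",
    "TrainedHead",
    "split_by_participant",
    "balance_and_shuffle",
    "train",
]


@dataclass(frozen=True)
class HeadConfig:
    """Hyperparameters of the prediction head and its training run."""

    input_dim: int = 1025
    hidden: tuple[int, ...] = (1024, 1024, 512)
    output_dim: int = 6
    l2: float = 1e-4            # penalty on the first two hidden layers' weights
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10          # early-stopping patience on validation loss
    standardize: bool = True    # z-score features with training-set statistics
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden"] = list(self.hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HeadConfig":
        d = dict(d)
        d["hidden"] = tuple(d["hidden"])
        return cls(**d)


@dataclass
class LabelledDataset:
    """Per-example (participant id, feature vector, subframe labels)."""

    participants: np.ndarray  # (n,) str
    features: np.ndarray      # (n, d) float
    labels: np.ndarray        # (n, 6) binary

    def __post_init__(self) -> None:
        self.participants = np.asarray(self.participants, dtype=object)
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        n = len(self.participants)
        if self.features.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("participants, features and labels must have equal length")

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def participant_ids(self) -> list[str]:
        return sorted(set(self.participants.tolist()))

    def subset(self, mask: np.ndarray) -> "LabelledDataset":
        return LabelledDataset(self.participants[mask], self.features[mask], self.labels[mask])

    @staticmethod
    def concatenate(parts: list["LabelledDataset"]) -> "LabelledDataset":
        return LabelledDataset(
            np.concatenate([p.participants for p in parts]),
            np.concatenate([p.features for p in parts]),
            np.concatenate([p.labels for p in parts]),
        )


def split_by_participant(
    dataset: LabelledDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[LabelledDataset, LabelledDataset]:
    """Partition participants (not examples) into train/validation sets.

    |train participants| = round(train_fraction * P), clamped so both sides
    keep at least one participant.
    """
    ids = dataset.participant_ids
    if len(ids) < 2:
        raise ValueError(f"need at least 2 participants to split; got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train_ids = {ids[i] for i in order[:n_train]}
    mask = np.array([p in train_ids for p in dataset.participants])
    return dataset.subset(mask), dataset.subset(~mask)


def balance_and_shuffle(labels: np.ndarray, epoch_seed: int) -> np.ndarray:
    """Balanced, shuffled example indices for one epoch.

    Frames whose label vector contains at least one 1 (swallow frames) and
    all-zero frames are equalized by random undersampling of the majority
    group without replacement; the combined order is then permuted.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels.any(axis=1))
    neg = np.flatnonzero(~labels.any(axis=1))
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "degenerate dataset: balancing needs both swallow and non-swallow frames "
            f"(got {len(pos)} swallow, {len(neg)} non-swallow)"
        )
    rng = np.random.default_rng(epoch_seed)
    m = min(len(pos), len(neg))
    chosen = np.concatenate(
        [rng.choice(pos, m, replace=False), rng.choice(neg, m, replace=False)]
    )
    return chosen[rng.permutation(len(chosen))]


def _init_weights(config: HeadConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Fan-in-scaled (He) initialization from the run seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    dims = [config.input_dim, *config.hidden, config.output_dim]
    weights = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        weights.append((w, np.zeros(d_out)))
    return weights


def _forward(weights, x):
    """Activations per layer plus the sigmoid output."""
    acts = [x]
    for w, b in weights[:-1]:
        x = np.maximum(x @ w + b, 0.0)
        acts.append(x)
    w, b = weights[-1]
    z = np.clip(acts[-1] @ w + b, -30.0, 30.0)  # keep outputs strictly in (0, 1)
    return acts, 1.0 / (1.0 + np.exp(-z))


def _backward(weights, acts, y, targets, l2):
    """Gradients of MSE + L2(first two hidden layers) w.r.t. all parameters."""
    n_out = y.shape[0] * y.shape[1]
    delta = (2.0 / n_out) * (y - targets) * y * (1.0 - y)
    grads = [None] * len(weights)
    for layer in range(len(weights) - 1, -1, -1):
        w, _b = weights[layer]
        gw = acts[layer].T @ delta
        if layer in (0, 1):
            gw = gw + 2.0 * l2 * w
        grads[layer] = (gw, delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ w.T) * (acts[layer] > 0.0)
    return grads


@dataclass
class TrainedHead:
    """Trained head weights plus everything needed to reproduce predictions."""

    weights: list[tuple[np.ndarray, np.ndarray]]
    config: HeadConfig
    backend_name: str
    backend_dim: int
    feature_mean: np.ndarray
    feature_std: np.ndarray
    history: dict = field(default_factory=dict)

    def predict(self, features: np.ndarray) -> np.ndarray:
        """Six subframe confidences in (0, 1) per input row."""
        x = np.asarray(features, dtype=np.float64)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != self.config.input_dim:
            raise ValueError(
                f"feature length {x.shape[1]} does not match head input_dim {self.config.input_dim}"
            )
        if self.config.standardize:
            x = (x - self.feature_mean) / self.feature_std
        _acts, y = _forward(self.weights, x)
        return y[0] if single else y

    def check_backend(self, backend: EmbeddingBackend) -> None:
        if backend.name != self.backend_name or backend.dim != self.backend_dim:
            raise ValueError(
                f"model artifact was trained against backend "
                f"{self.backend_name!r} (dim {self.backend_dim}); refusing to run with "
                f"{backend.name!r} (dim {backend.dim})"
            )

    def save(self, path: str | os.PathLike) -> None:
        """Write weights (.npz) and a JSON sidecar (.json) describing the run."""
        path = os.fspath(path)
        base, _ext = os.path.splitext(path)
        arrays = {"feature_mean": self.feature_mean, "feature_std": self.feature_std}
        for i, (w, b) in enumerate(self.weights):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez(base + ".npz", n_layers=len(self.weights), **arrays)
        sidecar = {
            "config": self.config.to_dict(),
            "backend": {"name": self.backend_name, "dim": self.backend_dim},
            "history": self.history,
        }
        with open(base + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TrainedHead":
        base, _ext = os.path.splitext(os.fspath(path))
        with np.load(base + ".npz") as data:
            n_layers = int(data["n_layers"])
            weights = [(data[f"w{i}"], data[f"b{i}"]) for i in range(n_layers)]
            mean, std = data["feature_mean"], data["feature_std"]
        with open(base + ".json") as fh:
            sidecar = json.load(fh)
        return cls(
            weights=weights,
            config=HeadConfig.from_dict(sidecar["config"]),
            backend_name=sidecar["backend"]["name"],
            backend_dim=int(sidecar["backend"]["dim"]),
            feature_mean=mean,
            feature_std=std,
            history=sidecar.get("history", {}),
        )


def _mse(weights, x, t):
    _acts, y = _forward(weights, x)
    return float(np.mean((y - t) ** 2))


def train(
    config: HeadConfig,
    train_ds: LabelledDataset,
    validation_ds: LabelledDataset,
    backend: EmbeddingBackend | None = None,
) -> TrainedHead:
    """Train the head; returns the epoch with the lowest validation loss.

    Fully deterministic given ``config.seed``: weight initialization, the
    per-epoch balancing/shuffling and the Adam updates all derive from it.
    """
    if len(train_ds) == 0 or len(validation_ds) == 0:
        raise ValueError("train and validation datasets must be non-empty")
    overlap = set(train_ds.participant_ids) & set(validation_ds.participant_ids)
    if overlap:
        raise ValueError(f"participant leakage between train and validation: {sorted(overlap)}")
    if train_ds.features.shape[1] != config.input_dim:
        raise ValueError(
            f"feature dim {train_ds.features.shape[1]} does not match config input_dim "
            f"{config.input_dim}"
        )
    if backend is not None and backend.dim + 1 != config.input_dim:
        raise ValueError("config.input_dim must equal backend.dim + 1")

    if config.standardize:
        mean = train_ds.features.mean(axis=0)
        std = np.maximum(train_ds.features.std(axis=0), 1e-8)
    else:
        mean = np.zeros(config.input_dim)
        std = np.ones(config.input_dim)
    x_train = (train_ds.features - mean) / std
    x_val = (validation_ds.features - mean) / std
    t_train = train_ds.labels.astype(np.float64)
    t_val = validation_ds.labels.astype(np.float64)

    weights = _init_weights(config)
    adam_m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    adam_v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = [(w.copy(), b.copy()) for w, b in weights]
    best_epoch = -1
    stale = 0

    for epoch in range(config.max_epochs):
        epoch_seed = int(
            np.random.SeedSequence([config.seed, 1000 + epoch]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        order = balance_and_shuffle(train_ds.labels, epoch_seed)
        batch_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, tb = x_train[idx], t_train[idx]
            acts, y = _forward(weights, xb)
            batch_losses.append(float(np.mean((y - tb) ** 2)))
            grads = _backward(weights, acts, y, tb, config.l2)
            step += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for layer in range(len(weights)):
                w, b = weights[layer]
                gw, gb = grads[layer]
                mw, mb = adam_m[layer]
                vw, vb = adam_v[layer]
                mw = beta1 * mw + (1 - beta1) * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vw = beta2 * vw + (1 - beta2) * gw**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                adam_m[layer] = (mw, mb)
                adam_v[layer] = (vw, vb)
                weights[layer] = (
                    w - lr_t * mw / (np.sqrt(vw) + eps),
                    b - lr_t * mb / (np.sqrt(vb) + eps),
                )
        val_loss = _mse(weights, x_val, t_val)
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = [(w.copy(), b.copy()) for w, b in weights]
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if config.patience > 0 and stale >= config.patience:
                break
    history["best_epoch"] = best_epoch

    return TrainedHead(
        weights=best_weights,
        config=config,
        backend_name=backend.name if backend is not None else "unspecified",
        backend_dim=backend.dim if backend is not None else config.input_dim - 1,
        feature_mean=mean,
        feature_std=std,
        history=history,
    )
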