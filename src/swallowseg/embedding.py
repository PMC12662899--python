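"""Frame embeddings via pluggable backends, plus ZCR concatenation.

Two backends satisfy the same contract (deterministic transform to a fixed
1024-dim vector):

* ``yamnet`` — adapter around the published pretrained audio-classification
  network (penultimate-layer embeddings). Optional: requires tensorflow-hub
  and a network download; never used by the test suite.
* ``mel-stats`` — deterministic, dependency-free summary of the log-mel patch
  projected to 1024 dims by a fixed seeded random linear map. This is the
  default offline backend.

The downstream head consumes ``embedding ++ [zcr]`` (length dim + 1).
"""

from __future__ import annotations

import abc

import numpy as np

from . import config

__all__ = [
    "BackendUnavailableError",
    "EmbeddingBackend",
    "MelStatsBackend",
    "YamnetBackend",
    "get_backend",
    "embed",
    "concat_features",
]


class BackendUnavailableError(RuntimeError):
    """Raised when a backend's runtime dependencies are missing."""


class EmbeddingBackend(abc.ABC):
    """Contract: a named, deterministic map from a frame to a dim-vector."""

    #: backend identifier recorded in model artifacts
    name: str
    #: embedding length, constant over the backend's lifetime
    dim: int
    #: "logmel" (consumes a 96x64 patch) or "waveform" (consumes raw samples)
    input_kind: str = "logmel"

    @abc.abstractmethod
    def transform(self, patch: np.ndarray) -> np.ndarray:
        """Map one frame input to a vector of length ``dim``."""


class MelStatsBackend(EmbeddingBackend):
    """Deterministic log-mel summary embedding.

    The patch is normalized per mel band before pooling: each band's
    temporal mean over the 96 steps is subtracted (the cepstral-mean-
    subtraction analog, removing static background level and color) and the
    result is divided by the band's temporal std (removing the band's
    fluctuation scale, which varies with background spectrum). Pooled
    statistics of this shape patch — per-band 10th/90th percentiles (robust
    to the spiky extremes the log-offset floor produces in low-energy bands)
    and the per-band mean over each of the six subframe-aligned 16-step time
    segments (the coarse temporal structure the subframe head needs to
    localize events within a frame) — are concatenated with the raw per-band
    std (64 dims of scale information): 64 + 2x64 + 6x64 = 576 values,
    projected to 1024 dims by a random linear map drawn once from a fixed
    seed, so artifacts are reproducible across machines.
    """

    name = "mel-stats"
    dim = config.EMBEDDING_DIM
    input_kind = "logmel"

    _STATS_DIM = 3 * config.N_MELS + config.N_SUBFRAMES * config.N_MELS

    def __init__(self, projection_seed: int = config.MELSTATS_PROJECTION_SEED):
        rng = np.random.default_rng(projection_seed)
        self._projection = rng.standard_normal((self._STATS_DIM, self.dim)) / np.sqrt(
            self._STATS_DIM
        )

    # STFT steps whose 25 ms window lies fully inside the frame's real
    # samples; the final two steps read into the tail zero-padding and are
    # excluded from pooling.
    _SUPPORTED_STEPS = 94

    def stats(self, patch: np.ndarray) -> np.ndarray:
        """The 576 pooled statistics, before projection."""
        patch = np.asarray(patch, dtype=np.float64)[: self._SUPPORTED_STEPS]
        centered = patch - patch.mean(axis=0)
        scale = centered.std(axis=0)
        shape = centered / np.maximum(scale, 1e-8)
        q10, q90 = np.quantile(shape, [0.10, 0.90], axis=0)
        # subframe-aligned segments: subframe i spans STFT steps 16i..16(i+1),
        # the last truncated to the supported steps
        step = config.N_PATCH_STEPS // config.N_SUBFRAMES
        seg_means = np.stack(
            [
                shape[i * step : min((i + 1) * step, self._SUPPORTED_STEPS)].mean(axis=0)
                for i in range(config.N_SUBFRAMES)
            ]
        )
        return np.concatenate([scale, q10, q90, seg_means.ravel()])

    def transform(self, patch: np.ndarray) -> np.ndarray:
        return self.stats(patch) @ self._projection


class YamnetBackend(EmbeddingBackend):
    """Adapter for the published pretrained audio network (optional).

    Consumes the raw 0.96 s waveform frame and returns the 1024-dim
    penultimate-layer embedding. Requires ``tensorflow`` + ``tensorflow_hub``
    and a one-time model download.
    """

    name = "yamnet"
    dim = config.EMBEDDING_DIM
    input_kind = "waveform"

    _HUB_URL = "https://tfhub.dev/google/yamnet/1"

    def __init__(self):
        try:
            import tensorflow_hub as hub  # type: ignore
        except ImportError as exc:
            raise BackendUnavailableError(
                "backend 'yamnet' is unavailable: tensorflow_hub is not installed "
                "(install the [yamnet] extra); use --backend mel-stats for offline runs"
            ) from exc
        self._model = hub.load(self._HUB_URL)

    def transform(self, patch: np.ndarray) -> np.ndarray:  # pragma: no cover - optional
        waveform = np.asarray(patch, dtype=np.float32)
        _scores, embeddings, _spec = self._model(waveform)
        return np.asarray(embeddings)[0].astype(np.float64)


_BACKENDS = {"mel-stats": MelStatsBackend, "yamnet": YamnetBackend}


def get_backend(name: str) -> EmbeddingBackend:
    """Instantiate a backend by name; unknown names list the choices."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}") from None
    return cls()


def embed(backend: EmbeddingBackend, patch: np.ndarray) -> np.ndarray:
    """Embed one frame input, validating shape and finiteness."""
    patch = np.asarray(patch, dtype=np.float64)
    if backend.input_kind == "logmel" and patch.shape != (
        config.N_PATCH_STEPS,
        config.N_MELS,
    ):
        raise ValueError(
            f"backend {backend.name!r} expects a ({config.N_PATCH_STEPS}, {config.N_MELS}) "
            f"log-mel patch; got shape {patch.shape}"
        )
    vec = np.asarray(backend.transform(patch), dtype=np.float64)
    if vec.shape != (backend.dim,):
        raise ValueError(f"backend {backend.name!r} returned shape {vec.shape}, expected ({backend.dim},)")
    if not np.all(np.isfinite(vec)):
        raise ValueError(f"backend {backend.name!r} returned non-finite values")
    return vec


def concat_features(embedding: np.ndarray, zcr: float) -> np.ndarray:
    """Append the ZCR scalar to the embedding: output length dim + 1."""
    if not 0.0 <= zcr <= 1.0:
        raise ValueError(f"zcr must lie in [0, 1]; got {zcr}")
    return np.concatenate([np.asarray(embedding, dtype=np.float64), [float(zcr)]])
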