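"""Participant-wise splitting, per-epoch balancing, head training and I/O."""

import numpy as np
import pytest

from swallowseg.embedding import MelStatsBackend
from swallowseg.model import (
    HeadConfig,
    LabelledDataset,
    TrainedHead,
    balance_and_shuffle,
    split_by_participant,
    train,
)

# a small head keeps trainer tests fast; the trainer code path is identical
_SMALL = dict(input_dim=20, hidden=(32, 32, 16))


def _dataset(rng, participants, n_per, input_dim=20, p_positive=0.5):
    ids, feats, labels = [], [], []
    for p in participants:
        for _ in range(n_per):
            ids.append(p)
            lab = np.zeros(6, dtype=np.int8)
            if rng.uniform() < p_positive:
                lab[rng.integers(0, 6)] = 1
            feats.append(rng.standard_normal(input_dim) + 2.0 * lab.sum())
            labels.append(lab)
    return LabelledDataset(np.array(ids, dtype=object), np.array(feats), np.array(labels))


class TestSplitByParticipant:
    def test_ten_participants_eight_two(self, rng):
        ds = _dataset(rng, [f"p{i}" for i in range(10)], 5)
        tr, va = split_by_participant(ds, 0.8, seed=3)
        assert len(set(tr.participants)) == 8
        assert len(set(va.participants)) == 2

    def test_two_participants_one_each(self, rng):
        ds = _dataset(rng, ["a", "b"], 4)
        tr, va = split_by_participant(ds, 0.8, seed=0)
        assert len(set(tr.participants)) == 1
        assert len(set(va.participants)) == 1

    def test_disjoint_for_any_seed(self, rng):
        ds = _dataset(rng, [f"p{i}" for i in range(7)], 3)
        for seed in range(5):
            tr, va = split_by_participant(ds, 0.8, seed=seed)
            assert not (set(tr.participants) & set(va.participants))
            assert len(tr) + len(va) == len(ds)

    def test_single_participant_rejected(self, rng):
        ds = _dataset(rng, ["only"], 5)
        with pytest.raises(ValueError):
            split_by_participant(ds, 0.8, seed=0)


class TestBalanceAndShuffle:
    def test_undersamples_majority(self, rng):
        labels = np.zeros((400, 6), dtype=np.int8)
        labels[:100, 0] = 1  # 100 swallow frames, 300 non-swallow
        idx = balance_and_shuffle(labels, epoch_seed=7)
        assert len(idx) == 200
        assert labels[idx].any(axis=1).sum() == 100

    def test_balanced_input_fully_retained(self, rng):
        labels = np.zeros((100, 6), dtype=np.int8)
        labels[:50, 2] = 1
        idx = balance_and_shuffle(labels, epoch_seed=7)
        assert sorted(idx) == list(range(100))
        assert not np.array_equal(idx, np.arange(100))  # order permuted

    def test_same_seed_same_order(self):
        labels = np.zeros((60, 6), dtype=np.int8)
        labels[::2, 1] = 1
        a = balance_and_shuffle(labels, epoch_seed=11)
        b = balance_and_shuffle(labels, epoch_seed=11)
        assert np.array_equal(a, b)

    def test_degenerate_dataset_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            balance_and_shuffle(np.zeros((10, 6), dtype=np.int8), epoch_seed=0)


class TestTraining:
    def test_learning_reduces_train_mse(self, rng):
        tr = _dataset(rng, ["a", "b"], 40)
        va = _dataset(rng, ["c"], 20)
        cfg = HeadConfig(**_SMALL, max_epochs=15, patience=0, seed=0)
        head = train(cfg, tr, va, backend=None)
        hist = head.history["train_loss"]
        assert hist[-1] < hist[0]

    def test_overfits_small_separable_set(self, rng):
        # 32 examples whose labels are a deterministic function of the input:
        # the hot subframe index is marked by a +3 shift in the matching dim
        def separable(participant, n):
            feats, labels = [], []
            for i in range(n):
                lab = np.zeros(6, dtype=np.int8)
                x = rng.standard_normal(20)
                if i % 2:
                    j = int(rng.integers(0, 6))
                    lab[j] = 1
                    x[j] += 3.0
                feats.append(x)
                labels.append(lab)
            return LabelledDataset(
                np.array([participant] * n, dtype=object), np.array(feats), np.array(labels)
            )

        tr, va = separable("a", 32), separable("b", 16)
        cfg = HeadConfig(**_SMALL, max_epochs=100, patience=0, seed=0)
        head = train(cfg, tr, va, backend=None)
        assert head.history["train_loss"][-1] < 0.05

    def test_bitwise_deterministic(self, rng):
        tr = _dataset(rng, ["a", "b"], 20)
        va = _dataset(rng, ["c"], 10)
        cfg = HeadConfig(**_SMALL, max_epochs=5, patience=0, seed=9)
        h1 = train(cfg, tr, va)
        h2 = train(cfg, tr, va)
        assert h1.history == h2.history
        for (w1, b1), (w2, b2) in zip(h1.weights, h2.weights):
            assert np.array_equal(w1, w2) and np.array_equal(b1, b2)

    def test_participant_leakage_rejected(self, rng):
        tr = _dataset(rng, ["a", "b"], 10)
        va = _dataset(rng, ["b"], 10)
        with pytest.raises(ValueError, match="leakage"):
            train(HeadConfig(**_SMALL), tr, va)

    def test_dimension_mismatch_rejected(self, rng):
        tr = _dataset(rng, ["a"], 10, input_dim=7)
        va = _dataset(rng, ["b"], 10, input_dim=7)
        with pytest.raises(ValueError, match="input_dim"):
            train(HeadConfig(**_SMALL), tr, va)

    def test_epoch_cap_respected(self, rng):
        tr = _dataset(rng, ["a"], 20)
        va = _dataset(rng, ["b"], 10)
        cfg = HeadConfig(**_SMALL, max_epochs=3, patience=0)
        head = train(cfg, tr, va)
        assert len(head.history["train_loss"]) == 3


class TestPredict:
    def test_output_range_and_shape(self, rng):
        tr = _dataset(rng, ["a", "b"], 15)
        va = _dataset(rng, ["c"], 10)
        head = train(HeadConfig(**_SMALL, max_epochs=2, patience=0), tr, va)
        out = head.predict(rng.standard_normal(20))
        assert out.shape == (6,)
        assert np.all((out > 0) & (out < 1))

    def test_zero_output_layer_gives_half(self):
        cfg = HeadConfig(**_SMALL)
        weights = [
            (np.zeros((20, 32)), np.zeros(32)),
            (np.zeros((32, 32)), np.zeros(32)),
            (np.zeros((32, 16)), np.zeros(16)),
            (np.zeros((16, 6)), np.zeros(6)),
        ]
        head = TrainedHead(weights, cfg, "mel-stats", 19, np.zeros(20), np.ones(20))
        assert np.allclose(head.predict(np.ones(20)), 0.5)

    def test_wrong_feature_length_rejected(self, rng):
        tr = _dataset(rng, ["a", "b"], 10)
        va = _dataset(rng, ["c"], 5)
        head = train(HeadConfig(**_SMALL, max_epochs=1, patience=0), tr, va)
        with pytest.raises(ValueError):
            head.predict(np.zeros(21))


class TestSerialization:
    def test_round_trip_identical_predictions(self, rng, tmp_path):
        tr = _dataset(rng, ["a", "b"], 15)
        va = _dataset(rng, ["c"], 10)
        head = train(HeadConfig(**_SMALL, max_epochs=3, patience=0, seed=4), tr, va)
        head.save(tmp_path / "model.npz")
        loaded = TrainedHead.load(tmp_path / "model.npz")
        probe = rng.standard_normal((8, 20))
        assert np.array_equal(head.predict(probe), loaded.predict(probe))
        assert loaded.config == head.config
        assert loaded.history["best_epoch"] == head.history["best_epoch"]

    def test_backend_mismatch_refused(self, rng, tmp_path):
        tr = _dataset(rng, ["a", "b"], 10)
        va = _dataset(rng, ["c"], 5)
        head = train(HeadConfig(**_SMALL, max_epochs=1, patience=0), tr, va,
                     backend=None)
        with pytest.raises(ValueError, match="backend"):
            head.check_backend(MelStatsBackend())
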