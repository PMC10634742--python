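"""Masked weighted loss, epoch accounting, scheduling, checkpointing."""

import math

import numpy as np
import pytest

from axonseg.labels import AXON, ClassWeights
from axonseg.nn import (
    PlateauScheduler,
    TrainConfig,
    UNetConfig,
    build_network,
    evaluate_loss,
    load_checkpoint,
    save_checkpoint,
    steps_per_epoch,
    train,
    weighted_loss,
)
from axonseg.sampling import VolumeSample


def brute_force_loss(prob, target, weights):
    """Per-voxel python loop oracle for the masked weighted BCE."""
    lookup = weights.as_lookup()
    total, n = 0.0, 0
    for p, t in zip(prob.ravel(), target.ravel()):
        w = lookup[t]
        if w == 0:
            continue
        y = 1.0 if t == AXON else 0.0
        total += w * -(y * math.log(p) + (1 - y) * math.log(1 - p))
        n += 1
    return total / n if n else 0.0


class TestWeightedLoss:
    def test_matches_brute_force_loop(self, rng):
        weights = ClassWeights()
        for _ in range(20):
            shape = tuple(rng.integers(2, 6, size=3))
            prob = rng.uniform(0.01, 0.99, shape)
            target = rng.integers(0, 5, shape)
            assert weighted_loss(prob, target, weights) == pytest.approx(
                brute_force_loss(prob, target, weights), abs=1e-10
            )

    def test_single_axon_voxel_half_probability(self):
        loss = weighted_loss(np.array([0.5]), np.array([AXON]))
        assert loss == pytest.approx(1.5 * math.log(2), abs=1e-12)  # ~1.0397

    def test_all_unlabeled_gives_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert weighted_loss(np.array([0.5, 0.9]), np.array([0, 0])) == 0.0

    def test_perfect_predictions_drive_loss_to_zero(self):
        target = np.array([2, 1, 4, 3])
        for eps in (1e-3, 1e-5):
            prob = np.where(target == AXON, 1 - eps, eps)
            assert weighted_loss(prob, target) < weighted_loss(
                np.where(target == AXON, 1 - 10 * eps, 10 * eps), target
            )
        assert weighted_loss(np.where(target == AXON, 1 - 1e-7, 1e-7), target) < 1e-5


class TestStepsPerEpoch:
    @pytest.mark.parametrize("n,b,expected", [(700, 6, 116), (100, 6, 16), (6, 6, 1), (5, 6, 1)])
    def test_floor_division_with_minimum_one(self, n, b, expected):
        assert steps_per_epoch(n, b) == expected

    def test_zero_batch_rejected(self):
        with pytest.raises(ValueError):
            steps_per_epoch(100, 0)


class TestPlateauScheduler:
    def test_flat_losses_reduce_lr_after_patience(self):
        sched = PlateauScheduler(1e-4, factor=0.1, patience=2)
        lrs = [sched.update(1.0) for _ in range(4)]
        # first epoch establishes the best; two stagnant epochs trigger the drop
        assert lrs == pytest.approx([1e-4, 1e-4, 1e-5, 1e-5])

    def test_improving_losses_keep_lr(self):
        sched = PlateauScheduler(1e-3, patience=1)
        lrs = [sched.update(loss) for loss in (1.0, 0.9, 0.8)]
        assert lrs == pytest.approx([1e-3, 1e-3, 1e-3])

    def test_lr_floors_at_min_lr(self):
        sched = PlateauScheduler(1e-4, factor=0.1, patience=1, min_lr=1e-6)
        for _ in range(10):
            lr = sched.update(1.0)
        assert lr == pytest.approx(1e-6)


def _toy_samples(rng, n=8, size=8, out=4):
    """Windows whose targets mark bright voxels as axons — learnable."""
    samples = []
    m = (size - out) // 2
    for _ in range(n):
        img = rng.uniform(0, 2000, (size,) * 3)
        bright = rng.random((size,) * 3) < 0.1
        img[bright] = 40000.0
        target = np.ones((out,) * 3, dtype=np.uint8)
        target[bright[m : m + out, m : m + out, m : m + out]] = AXON
        samples.append(VolumeSample(img.astype(np.uint16), target))
    return samples


class TestTrainLoop:
    def test_loss_decreases_on_learnable_toy_data(self, rng):
        net = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=0))
        samples = _toy_samples(rng)
        cfg = TrainConfig(epochs=5, batch_size=4, learning_rate=1e-2, seed=0)
        result = train(net, samples, samples[:4], cfg)
        assert len(result.history) == 5
        assert result.history[-1].train_loss < result.history[0].train_loss

    def test_fixed_schedule_keeps_lr_constant(self, rng):
        net = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=0))
        samples = _toy_samples(rng, n=4)
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=1e-3, seed=0)
        result = train(net, samples, samples, cfg)
        assert {rec.lr for rec in result.history} == {1e-3}

    def test_plateau_schedule_reduces_lr_in_history(self, rng):
        import warnings

        net = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=0))
        # fully unlabeled validation targets: validation loss is constant 0,
        # so after the first epoch it never improves and the plateau fires
        img = np.zeros((8, 8, 8), dtype=np.uint16)
        unlabeled = np.zeros((4, 4, 4), dtype=np.uint8)
        train_samples = _toy_samples(rng, n=4)
        val_samples = [VolumeSample(img, unlabeled)] * 2
        cfg = TrainConfig(
            epochs=6, batch_size=4, learning_rate=1e-4,
            scheduler="plateau", plateau_patience=2, seed=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            result = train(net, train_samples, val_samples, cfg)
        lrs = [rec.lr for rec in result.history]
        assert lrs[:3] == [1e-4] * 3  # patience epochs at the original rate
        assert lrs[3] == pytest.approx(1e-5)  # reduced after two stagnant epochs
        assert result.history[-1].lr < 1e-4

    def test_best_checkpoint_reproduces_recorded_val_loss(self, rng, tmp_path):
        net = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=0))
        samples = _toy_samples(rng)
        cfg = TrainConfig(epochs=4, batch_size=4, learning_rate=1e-2, seed=0)
        result = train(net, samples, samples[:4], cfg, checkpoint_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "history.csv").exists()
        fresh = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=9))
        load_checkpoint(fresh, tmp_path / "best.npz")
        reloaded = evaluate_loss(fresh, samples[:4], cfg)
        assert reloaded == pytest.approx(result.best_val_loss, abs=1e-6)

    def test_empty_generator_rejected(self):
        net = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=0))
        cfg = TrainConfig(epochs=1, batch_size=2)
        with pytest.raises(ValueError):
            train(net, [], [], cfg)

    def test_callable_generator_is_redrawn_each_epoch(self, rng):
        calls = []

        def gen():
            calls.append(1)
            return _toy_samples(np.random.default_rng(len(calls)), n=4)

        net = build_network(UNetConfig(depth=2, base_filters=2, input_size=8, margin=2, seed=0))
        cfg = TrainConfig(epochs=3, batch_size=4, seed=0)
        train(net, gen, _toy_samples(rng, n=2), cfg)
        assert len(calls) == 3
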