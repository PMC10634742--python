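"""Masked class-weighted training of the segmentation network.

The loss is a per-voxel binary cross-entropy against the axon indicator
(code 2 is positive; background, artifact and edge are negatives), with
each voxel weighted by its label class — axons 1.5, background 0.2,
artifacts 0.8, edges 0.05 — and unlabeled voxels carrying weight zero,
which masks un-annotated slices out of the objective entirely. The mean
runs over the voxels with nonzero weight.

Fine-tuning uses Adam with either a fixed learning rate or a
reduce-on-plateau schedule (multiply by 0.1 after `patience` epochs
without validation improvement). The checkpoint kept is the epoch with
the lowest weighted validation loss.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from ..labels import AXON, ClassWeights
from ..sampling import VolumeSample
from .layers import DTYPE, Parameter
from .network import UNet3D

_EPS = 1e-7


def weighted_loss(
    prob: np.ndarray, target: np.ndarray, weights: ClassWeights | None = None
) -> float:
    """Mean class-weighted BCE over nonzero-weight voxels.

    ``prob`` holds per-voxel axon probabilities, ``target`` the label
    codes. Returns 0 (with a warning) when every voxel is unlabeled.
    """
    loss, _ = _loss_and_grad(prob, target, weights or ClassWeights(), need_grad=False)
    return loss


def _loss_and_grad(
    prob: np.ndarray,
    target: np.ndarray,
    weights: ClassWeights,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    prob = np.asarray(prob, dtype=DTYPE)
    target = np.asarray(target)
    if prob.shape != target.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs target {target.shape}")
    w = weights.as_lookup()[target]
    n_eff = int(np.count_nonzero(w))
    if n_eff == 0:
        warnings.warn("all voxels unlabeled; loss is 0", stacklevel=3)
        return 0.0, (np.zeros_like(prob) if need_grad else None)
    p = np.clip(prob, _EPS, 1.0 - _EPS)
    y = (target == AXON).astype(DTYPE)
    loss = float(np.sum(w * -(y * np.log(p) + (1.0 - y) * np.log1p(-p))) / n_eff)
    if not need_grad:
        return loss, None
    grad = w * (p - y) / (p * (1.0 - p)) / n_eff
    return loss, grad


def steps_per_epoch(n_volumes: int, batch_size: int) -> int:
    """Optimisation steps per epoch: floor(n_volumes / batch_size), min 1."""
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    if n_volumes <= 0:
        raise ValueError("n_volumes must be positive")
    return max(1, n_volumes // batch_size)


class Adam:
    """Adam on the trainable parameters only; frozen ones are never touched."""

    def __init__(
        self,
        params: Sequence[Parameter],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self, lr: float) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class PlateauScheduler:
    """Reduce-on-plateau: lr *= factor after `patience` stagnant epochs."""

    def __init__(
        self, lr: float, factor: float = 0.1, patience: int = 10, min_lr: float = 1e-6
    ) -> None:
        if not 0.0 < factor < 1.0:
            raise ValueError("factor must lie in (0, 1)")
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self._best = np.inf
        self._wait = 0

    def update(self, val_loss: float) -> float:
        """Record an epoch's validation loss; return the lr for the next epoch."""
        if val_loss < self._best:
            self._best = val_loss
            self._wait = 0
        else:
            self._wait += 1
            if self._wait >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self._wait = 0
        return self.lr


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 6
    learning_rate: float = 1e-3
    scheduler: str = "fixed"  # "fixed" | "plateau"
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    min_lr: float = 1e-6
    class_weights: ClassWeights = field(default_factory=ClassWeights)
    input_scale: float = 1.0 / 65535.0  # applied to integer-typed inputs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.scheduler not in ("fixed", "plateau"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    lr: float


@dataclass
class TrainResult:
    history: list[EpochRecord]
    best_epoch: int
    best_val_loss: float
    best_state: dict[str, np.ndarray]


def _materialize(
    data: Sequence[VolumeSample] | Callable[[], Iterable[VolumeSample]],
) -> list[VolumeSample]:
    if callable(data):
        return list(data())
    return list(data)


def _as_batch(samples: Sequence[VolumeSample], scale: float) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for s in samples:
        x = np.asarray(s.input)
        if np.issubdtype(x.dtype, np.integer):
            x = x.astype(DTYPE) * scale
        xs.append(x.astype(DTYPE, copy=False))
        ys.append(np.asarray(s.target))
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


def evaluate_loss(
    network: UNet3D,
    samples: Sequence[VolumeSample],
    config: TrainConfig,
) -> float:
    """Weighted validation loss in eval mode, averaged over batches."""
    losses = []
    for i in range(0, len(samples), config.batch_size):
        x, y = _as_batch(samples[i : i + config.batch_size], config.input_scale)
        prob = network.forward(x, training=False)
        loss, _ = _loss_and_grad(prob, y, config.class_weights, need_grad=False)
        losses.append(loss)
    return float(np.mean(losses))


def train(
    network: UNet3D,
    train_data: Sequence[VolumeSample] | Callable[[], Iterable[VolumeSample]],
    val_data: Sequence[VolumeSample] | Callable[[], Iterable[VolumeSample]],
    config: TrainConfig,
    checkpoint_dir: str | Path | None = None,
) -> TrainResult:
    """Run the fine-tuning loop and keep the lowest-validation-loss state.

    ``train_data``/``val_data`` are sequences of :class:`VolumeSample`
    or zero-argument callables returning a fresh iterable per epoch (use
    a callable to re-draw and re-augment samples every epoch). Integer
    inputs are scaled by ``config.input_scale`` (1/65535 by default);
    float inputs are taken as already normalised.
    """
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(network.parameters())
    lr = config.learning_rate
    scheduler = (
        PlateauScheduler(
            lr, config.plateau_factor, config.plateau_patience, config.min_lr
        )
        if config.scheduler == "plateau"
        else None
    )
    history: list[EpochRecord] = []
    best_val = np.inf
    best_epoch = -1
    best_state: dict[str, np.ndarray] = {k: v.copy() for k, v in network.state_dict().items()}

    val_samples = _materialize(val_data)
    for epoch in range(config.epochs):
        samples = _materialize(train_data)
        if not samples:
            raise ValueError("training generator yielded no samples")
        n_steps = steps_per_epoch(len(samples), config.batch_size)
        order = rng.permutation(len(samples))
        epoch_losses = []
        for step in range(n_steps):
            idx = order[step * config.batch_size : (step + 1) * config.batch_size]
            if len(idx) == 0:
                idx = order[: config.batch_size]
            x, y = _as_batch([samples[i] for i in idx], config.input_scale)
            network.zero_grad()
            prob = network.forward(x, training=True)
            loss, grad = _loss_and_grad(prob, y, config.class_weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss {loss} at epoch {epoch}, step {step}"
                )
            network.backward(grad)
            optimizer.step(lr)
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        val_loss = evaluate_loss(network, val_samples, config)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append(EpochRecord(epoch, train_loss, val_loss, lr))
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in network.state_dict().items()}
        if scheduler is not None:
            lr = scheduler.update(val_loss)

    result = TrainResult(history, best_epoch, float(best_val), best_state)
    if checkpoint_dir is not None:
        save_checkpoint(network, result, config, checkpoint_dir)
    return result


def save_checkpoint(
    network: UNet3D,
    result: TrainResult,
    config: TrainConfig,
    out_dir: str | Path,
) -> Path:
    """Write best weights (.npz), a JSON sidecar, and the training CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckpt = out / "best.npz"
    np.savez_compressed(ckpt, **result.best_state)
    sidecar = {
        "best_epoch": result.best_epoch,
        "best_val_loss": result.best_val_loss,
        "network": {
            "depth": network.config.depth,
            "base_filters": network.config.base_filters,
            "input_size": network.config.input_size,
            "margin": network.config.margin,
            "use_batchnorm": network.config.use_batchnorm,
            "seed": network.config.seed,
        },
        "train": {
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "scheduler": config.scheduler,
            "seed": config.seed,
        },
    }
    (out / "best.json").write_text(json.dumps(sidecar, indent=2))
    with open(out / "history.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "train_loss", "val_loss", "lr"])
        for rec in result.history:
            writer.writerow([rec.epoch, rec.train_loss, rec.val_loss, rec.lr])
    return ckpt


def load_checkpoint(network: UNet3D, path: str | Path) -> UNet3D:
    """Restore weights saved by :func:`save_checkpoint` into ``network``."""
    with np.load(path) as data:
        network.load_state_dict({k: data[k] for k in data.files})
    return network
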