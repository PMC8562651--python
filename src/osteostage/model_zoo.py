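"""Classifier architectures, training schedules, and the training loop.

Four residual classifiers are exposed: 2D ResNet-50 and ResNeXt-50
(cardinality 32) for patch analysis, and 3D ResNet-18 / ResNet-50 (3x3x3
first layer) for volumetric lesions. Training minimises 2-class
cross-entropy over the softmax pair with plain SGD, a stepwise learning
rate (lr = lr0 * factor^floor(epoch/every)) and L2 weight regularisation.
Inputs are rescaled from 8-bit to [0, 1] at the loader; there is no
dataset-mean normalisation. A width multiplier below 1 shrinks channel
counts for desk-scale experiments without altering depth or topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from .nn.layers import SGD, cross_entropy, softmax
from .nn.resnet import ResNet, resnet18_3d, resnet50_2d, resnet50_3d, resnext50_2d_c32
from .types import MALIGNANT, Sample

ARCHS = {
    "resnet50_2d": resnet50_2d,
    "resnext50_2d_c32": resnext50_2d_c32,
    "resnet18_3d": resnet18_3d,
    "resnet50_3d": resnet50_3d,
}


@dataclass(frozen=True)
class ArchSpec:
    """Which classifier to build and at what width."""

    id: str
    width_mult: float = 1.0
    in_channels: Optional[int] = None  # default: 3 for 2D nets, 1 for 3D
    n_outputs: int = 2
    cardinality: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.id not in ARCHS:
            raise ValueError(f"unknown architecture {self.id!r}; choose from {sorted(ARCHS)}")
        if self.n_outputs != 2:
            raise ValueError("classifiers emit a 2-way (benign, malignant) score vector")

    @property
    def is_3d(self) -> bool:
        return self.id.endswith("_3d")


@dataclass
class TrainConfig:
    """SGD schedule: stepwise learning-rate decay with optional early stop."""

    lr0: float = 1e-3
    lr_drop_factor: float = 0.8
    lr_drop_every_epochs: int = 7
    weight_decay: float = 2e-4
    max_epochs: int = 100
    early_stop_patience: Optional[int] = None
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not (0.0 < self.lr_drop_factor <= 1.0):
            raise ValueError("lr_drop_factor must lie in (0, 1]")

    def lr_at(self, epoch: int) -> float:
        return self.lr0 * self.lr_drop_factor ** (epoch // self.lr_drop_every_epochs)


def default_train_config(experiment: str) -> TrainConfig:
    """Published training schedules for the three experiment families."""
    if experiment == "exp1_2d":
        return TrainConfig(lr0=1e-3, lr_drop_factor=0.8, lr_drop_every_epochs=7,
                           weight_decay=2e-4, max_epochs=100)
    if experiment == "exp4_3d":
        return TrainConfig(lr0=3e-3, lr_drop_factor=0.85, lr_drop_every_epochs=5,
                           weight_decay=2e-4, max_epochs=100, early_stop_patience=10)
    if experiment == "exp5_3d_k":
        return TrainConfig(lr0=5e-3, lr_drop_factor=0.85, lr_drop_every_epochs=5,
                           weight_decay=2e-4, max_epochs=100, early_stop_patience=10)
    raise ValueError(f"unknown experiment {experiment!r}")


def build_model(spec: ArchSpec) -> ResNet:
    in_ch = spec.in_channels if spec.in_channels is not None else (1 if spec.is_3d else 3)
    kwargs = dict(width_mult=spec.width_mult, in_channels=in_ch, seed=spec.seed)
    if spec.id == "resnext50_2d_c32":
        kwargs["cardinality"] = spec.cardinality
    return ARCHS[spec.id](**kwargs)


def sample_to_input(sample: Sample, target_hw: Optional[int] = None) -> np.ndarray:
    """Network input from a sample: (3, H, W) for 2D/2.5D, (1, X, Y, Z) for 3D.

    2D (single-plane) samples are replicated into 3 channels so one 2D
    architecture serves both patch flavours. ``target_hw`` bilinearly
    resizes the in-plane dimensions (this is where tight rectangular crops
    get their aspect distortion). Values are rescaled to [0, 1].
    """
    px = sample.pixels.astype(np.float32) / 255.0
    if px.ndim == 2:
        px = np.stack([px, px, px], axis=0)
    if px.ndim == 3 and sample.strategy in ("I", "J", "K", "L"):
        if target_hw is not None and px.shape[:2] != (target_hw, target_hw):
            px = resize(px, (target_hw, target_hw, px.shape[2]), order=1,
                        preserve_range=True, anti_aliasing=False).astype(np.float32)
        return px[None]
    if target_hw is not None and px.shape[1:] != (target_hw, target_hw):
        px = np.stack(
            [resize(p, (target_hw, target_hw), order=1, preserve_range=True,
                    anti_aliasing=False) for p in px], axis=0
        ).astype(np.float32)
    return px


def batch_inputs(samples: Sequence[Sample], target_hw: Optional[int] = None) -> np.ndarray:
    return np.stack([sample_to_input(s, target_hw) for s in samples], axis=0)


@dataclass
class History:
    epochs: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _labels_to_int(labels: Sequence[str]) -> np.ndarray:
    return np.array([1 if l == MALIGNANT else 0 for l in labels], dtype=np.int64)


def train(
    model: ResNet,
    train_x: np.ndarray,
    train_labels: Sequence[str],
    valid_x: Optional[np.ndarray],
    valid_labels: Optional[Sequence[str]],
    config: TrainConfig,
    sample_weight: Optional[np.ndarray] = None,
) -> History:
    """SGD training with the stepwise schedule; reproducible for a fixed seed.

    ``train_x`` is a pre-batched input array (use :func:`batch_inputs`).
    Early stopping, when configured, halts after ``early_stop_patience``
    epochs without validation-loss improvement and keeps the last weights.
    """
    if len(train_x) == 0:
        raise ValueError("empty training set")
    y = _labels_to_int(train_labels)
    y_val = _labels_to_int(valid_labels) if valid_labels is not None else None
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.params(), config.lr0, config.weight_decay)
    hist = History()
    best_val = np.inf
    since_best = 0
    for epoch in range(config.max_epochs):
        opt.lr = config.lr_at(epoch)
        model.set_training(True)
        order = rng.permutation(len(train_x))
        losses, weights = [], []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            opt.zero_grad()
            logits = model(train_x[idx])
            sw = sample_weight[idx] if sample_weight is not None else None
            loss, dlogits = cross_entropy(logits, y[idx], sw)
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            weights.append(len(idx))
        train_loss = float(np.average(losses, weights=weights))
        valid_loss = np.nan
        if valid_x is not None and len(valid_x):
            model.set_training(False)
            logits = model(valid_x)
            valid_loss, _ = cross_entropy(logits, y_val)
        hist.epochs.append(epoch)
        hist.lr.append(opt.lr)
        hist.train_loss.append(train_loss)
        hist.valid_loss.append(float(valid_loss))
        if not np.isnan(valid_loss) and valid_loss < best_val - 1e-9:
            best_val = valid_loss
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if config.early_stop_patience is not None and since_best >= config.early_stop_patience:
            break
    model.set_training(False)
    return hist


def predict_batch(model: ResNet, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """(benign, malignant) probability rows, softmax-normalised, input order."""
    model.set_training(False)
    outs = []
    for i in range(0, len(x), batch_size):
        outs.append(softmax(model(x[i : i + batch_size]).astype(np.float64)))
    return np.concatenate(outs, axis=0)
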