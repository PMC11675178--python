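"""Two-stage training: voxel-wise segmentation first, then a frozen-backbone
regression head for the three morphometric measurements.

Stage 1 trains every parameter with voxel-wise cross-entropy on (image,
mask) pairs, logging per-epoch train/validation accuracy, macro F1, kappa,
MCC and loss, and retaining the best-validation checkpoint.  Stage 2 freezes
the backbone — enforced structurally: only head parameters are ever handed
to the optimizer, and the head is trained on cached backbone features — and
fits the head with mean squared error against reference (thickness, height,
width) triplets.

Whole eggs are fed as single volumes (no patch sampling).  Inputs are
expected on the normalized [0, 255] scale and are divided by 255 before
entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .evaluate import confusion_matrix, metrics_from_confusion
from .nets import _BaseNet
from .volume_io import CTVolume, LabelVolume


@dataclass
class TrainConfig:
    """Hyperparameters for both stages.

    The reference protocol uses Adam throughout, cross-entropy (stage 1) /
    MSE (stage 2), learning rate 1e-4 (U-Net) or 1e-5 (FCN) for 1000 epochs,
    batch size 25 (U-Net) / 15 (FCN), and a stage-2 learning rate of 1e-5
    for 80 (U-Net) / 1000 (FCN) epochs.  Desk-scale phantom runs use far
    fewer epochs and a larger learning rate; all values are free here.
    """

    learning_rate: float = 1e-4
    epochs: int = 1000
    batch_size: int = 25
    learning_rate_stage2: float = 1e-5
    epochs_stage2: int = 80
    seed: int = 0
    class_weights: np.ndarray | None = None  # optional CE weighting, off by default
    joint_loss_weight: float | None = None  # single-stage joint training (see note)

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.learning_rate_stage2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.epochs_stage2 < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(samples: list, spec: SplitSpec):
    """Deterministic disjoint train/val/test split.

    Validation and test sizes are the floored fractions; the remainder goes
    to training (122 samples at 80/10/10 gives 98/12/12).
    """
    n = len(samples)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    n_val = int(n * spec.fractions[1])
    n_test = int(n * spec.fractions[2])
    perm = np.random.default_rng(spec.seed).permutation(n)
    val_idx = perm[:n_val]
    test_idx = perm[n_val:n_val + n_test]
    train_idx = perm[n_val + n_test:]
    pick = lambda idx: [samples[i] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


@dataclass
class TrainResult:
    model: _BaseNet
    history: pd.DataFrame
    best_epoch: int = -1
    best_state: list = field(default_factory=list, repr=False)


def _as_arrays(samples):
    """Convert (volume, mask) pairs to network-ready arrays."""
    xs, ys = [], []
    shape = None
    for i, (vol, mask) in enumerate(samples):
        x = vol.intensities if isinstance(vol, CTVolume) else np.asarray(vol)
        y = mask.codes if isinstance(mask, LabelVolume) else np.asarray(mask)
        if x.shape != y.shape:
            raise ValueError(f"sample {i}: image shape {x.shape} != mask shape {y.shape}")
        if shape is None:
            shape = x.shape
        elif x.shape != shape:
            raise ValueError(f"sample {i}: shape {x.shape} differs from first sample {shape}")
        xs.append(np.asarray(x, dtype=nn.FLOAT) / 255.0)
        ys.append(y.astype(np.int64))
    return np.stack(xs)[:, None], np.stack(ys)


def _weighted_ce(scores, labels, weights):
    if weights is None:
        return nn.softmax_cross_entropy(scores, labels)
    p = nn.softmax(scores, axis=1)
    k = scores.shape[1]
    flat_p = p.transpose(0, 2, 3, 4, 1).reshape(-1, k)
    flat_l = labels.reshape(-1)
    wv = np.asarray(weights, dtype=np.float64)[flat_l]
    wsum = wv.sum()
    loss = float(-(wv * np.log(flat_p[np.arange(flat_l.size), flat_l] + 1e-12)).sum() / wsum)
    g = flat_p.copy()
    g[np.arange(flat_l.size), flat_l] -= 1.0
    g *= (wv / wsum)[:, None]
    g = g.reshape(scores.shape[0], *scores.shape[2:], k).transpose(0, 4, 1, 2, 3)
    return loss, np.ascontiguousarray(g, dtype=nn.FLOAT)


def _eval_split(model, x, y, batch: int = 4):
    cm = None
    loss_sum = 0.0
    for i in range(0, len(x), batch):
        scores = model.forward(x[i:i + batch], train=False)
        loss, _ = nn.softmax_cross_entropy(scores, y[i:i + batch])
        loss_sum += loss * len(x[i:i + batch])
        pred = scores.argmax(axis=1)
        c = confusion_matrix(y[i:i + batch], pred, scores.shape[1])
        cm = c if cm is None else cm + c
    m = metrics_from_confusion(cm)
    m["loss"] = loss_sum / len(x)
    return m


def train_stage1(model: _BaseNet, train_set, val_set, config: TrainConfig,
                 restore_best: bool = True) -> TrainResult:
    """Stage 1: train all backbone parameters for semantic segmentation."""
    x_tr, y_tr = _as_arrays(train_set)
    x_va, y_va = _as_arrays(val_set) if val_set else (None, None)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.backbone_params(), lr=config.learning_rate)

    rows = []
    best_acc, best_epoch, best_state = -1.0, -1, []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        cm = None
        loss_sum = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            scores = model.forward(xb, train=True)
            loss, g = _weighted_ce(scores, yb, config.class_weights)
            opt.zero_grad()
            model.backward(g)
            opt.step()
            loss_sum += loss * len(idx)
            c = confusion_matrix(yb, scores.argmax(axis=1), scores.shape[1])
            cm = c if cm is None else cm + c
        m = metrics_from_confusion(cm)
        rows.append({"epoch": epoch, "split": "train", "loss": loss_sum / len(x_tr),
                     "accuracy": m["accuracy"], "f1": m["macro_f1"],
                     "kappa": m["kappa"], "mcc": m["mcc"]})
        if x_va is not None:
            mv = _eval_split(model, x_va, y_va)
            rows.append({"epoch": epoch, "split": "val", "loss": mv["loss"],
                         "accuracy": mv["accuracy"], "f1": mv["macro_f1"],
                         "kappa": mv["kappa"], "mcc": mv["mcc"]})
            if mv["accuracy"] > best_acc:
                best_acc, best_epoch = mv["accuracy"], epoch
                best_state = nn.get_state(model.backbone_params())

    if restore_best and best_state:
        nn.set_state(model.backbone_params(), best_state)
    return TrainResult(model, pd.DataFrame(rows), best_epoch, best_state)


def train_stage2(model: _BaseNet, train_set, config: TrainConfig) -> TrainResult:
    """Stage 2: freeze the backbone, train only the measurement head.

    ``train_set`` is a list of (volume, (thickness, height, width)) pairs.
    The backbone runs once per sample in eval mode to produce the pooled
    decoder feature; the head is then fit on those cached features, so
    backbone parameters are untouched by construction (and verifiable by
    checksum).
    """
    if model.head is None:
        model.attach_head(np.random.default_rng(config.seed))
    feats, targets = [], []
    for i, (vol, meas) in enumerate(train_set):
        if meas is None or len(meas) != 3:
            raise ValueError(f"sample {i} lacks the (thickness, height, width) triplet")
        x = vol.intensities if isinstance(vol, CTVolume) else np.asarray(vol)
        feats.append(model.pooled_head_feature(
            np.asarray(x, dtype=nn.FLOAT)[None, None] / 255.0)[0])
        targets.append(np.asarray(meas, dtype=nn.FLOAT))
    feats = np.stack(feats)
    targets = np.stack(targets)

    rng = np.random.default_rng(config.seed + 1)
    opt = nn.Adam(model.head_params(), lr=config.learning_rate_stage2)
    rows = []
    for epoch in range(config.epochs_stage2):
        order = rng.permutation(len(feats))
        loss_sum = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            pred = model.head.forward_pooled(feats[idx], train=True)
            loss, g = nn.mse_loss(pred, targets[idx])
            opt.zero_grad()
            model.head.backward_pooled(g)
            opt.step()
            loss_sum += loss * len(idx)
        rows.append({"epoch": epoch, "split": "train", "loss": loss_sum / len(feats)})
    return TrainResult(model, pd.DataFrame(rows))


def train_joint(model: _BaseNet, train_set, config: TrainConfig) -> TrainResult:
    """Single-stage joint training of segmentation and head with a weighted
    sum of both losses.

    Kept only to document that this route underperforms the two-stage
    protocol; it is not part of the supported pipeline.
    """
    w = config.joint_loss_weight if config.joint_loss_weight is not None else 0.5
    if model.head is None:
        model.attach_head(np.random.default_rng(config.seed))
    xs, ys = _as_arrays([(v, m) for v, m, _ in train_set])
    ts = np.stack([np.asarray(t, dtype=nn.FLOAT) for _, _, t in train_set])
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(xs))
        loss_sum = 0.0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            scores, meas = model.forward_with_head(xs[idx], train=True)
            l1, g1 = nn.softmax_cross_entropy(scores, ys[idx])
            l2, g2 = nn.mse_loss(meas, ts[idx])
            opt.zero_grad()
            gfeat = model.head.gap.backward(model.head.backward_pooled(w * g2))
            model.backward((1 - w) * g1, g_head_feature=gfeat)
            opt.step()
            loss_sum += ((1 - w) * l1 + w * l2) * len(idx)
        rows.append({"epoch": epoch, "split": "train", "loss": loss_sum / len(xs)})
    return TrainResult(model, pd.DataFrame(rows))


def segment(model: _BaseNet, vol: CTVolume) -> LabelVolume:
    """Segment one egg volume (normalized [0, 255] scale) into class codes."""
    codes = model.predict(np.asarray(vol.intensities, dtype=nn.FLOAT) / 255.0)
    return LabelVolume(codes, vol.spacing)
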