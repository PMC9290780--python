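"""24-way chromosome classification: rotation augmentation, a small
convolutional backbone, and the training protocol (Adam, cross-entropy,
per-epoch shuffling, early stopping on validation accuracy).

Defaults follow the study protocol: batch size 40, at most 100 epochs,
early-stop patience 21, initial learning rate 5e-4, and 24 rotations of
15 degrees per training image.  The working backbone is ``small_cnn``
(three conv/pool blocks, global average pooling, a dense 24-way head);
the large ImageNet-era backbones are accepted in the config enum for
interface compatibility but require a deep-learning framework and
pretrained weights that this package does not ship, so selecting them
raises a clear error.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import rotate as nd_rotate

from .nn import Adam, Conv2d, Dense, GlobalAvgPool, MaxPool2, ReLU

__all__ = ["TrainConfig", "ClassifierState", "augment_rotations",
           "augment_dataset", "train_classifier", "predict",
           "save_classifier", "load_classifier"]

BACKBONES = ("small_cnn", "inception_resnet_v2", "resnet50", "xception",
             "vgg19")


@dataclass
class TrainConfig:
    batch_size: int = 40
    max_epochs: int = 100
    patience: int = 21
    learning_rate: float = 5e-4
    backbone: str = "small_cnn"
    transfer_learning: bool = False
    rotation_count: int = 24
    rotation_step_degrees: float = 15.0
    keep_original: bool = True
    n_classes: int = 24
    channels: tuple[int, ...] = (8, 16, 32)
    seed: int = 0

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if abs(self.rotation_count * self.rotation_step_degrees - 360.0) > 1e-9:
            raise ValueError("rotation_count * rotation_step_degrees must "
                             "cover a full turn (360 degrees)")
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")


class ClassifierState:
    """small_cnn parameters plus the 24-way head and label convention
    (0 = Y, 1-22 = autosomes, 23 = X)."""

    def __init__(self, config: TrainConfig):
        if config.backbone != "small_cnn":
            raise NotImplementedError(
                f"backbone {config.backbone!r} needs a deep-learning "
                "framework and pretrained weights; use 'small_cnn'")
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.channels
        self.convs = []
        cin = 1
        for c in chans:
            self.convs.append(Conv2d(cin, c, 3, rng))
            cin = c
        self.head = Dense(chans[-1], config.n_classes, rng)
        self.relu, self.pool, self.gap = ReLU(), MaxPool2(), GlobalAvgPool()

    def parameters(self):
        ps = []
        for conv in self.convs:
            ps.extend(conv.parameters())
        ps.extend(self.head.parameters())
        return ps

    def forward(self, x: np.ndarray):
        caches = []
        h = x
        for conv in self.convs:
            h, c1 = conv.forward(h)
            h, c2 = self.relu.forward(h)
            h, c3 = self.pool.forward(h)
            caches.append((c1, c2, c3))
        feats, cg = self.gap.forward(h)
        logits, ch = self.head.forward(feats)
        return logits, (caches, cg, ch)

    def backward(self, cache, glogits):
        caches, cg, ch = cache
        g = self.head.backward(ch, glogits)
        g = self.gap.backward(cg, g)
        for conv, (c1, c2, c3) in zip(reversed(self.convs), reversed(caches)):
            g = self.pool.backward(c3, g)
            g = self.relu.backward(c2, g)
            g = conv.backward(c1, g)
        return g


def augment_rotations(image: np.ndarray, config: TrainConfig) -> list[np.ndarray]:
    """``rotation_count`` copies rotated about the centre by k*step
    degrees (k = 1..count), zero-filled corners, dims preserved."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("rotation augmentation expects a square image")
    out = []
    for k in range(1, config.rotation_count + 1):
        angle = k * config.rotation_step_degrees
        rot = nd_rotate(image.astype(np.float64), angle, reshape=False,
                        order=1, mode="constant", cval=0.0)
        out.append(np.clip(np.round(rot), 0, 255).astype(image.dtype))
    return out


def augment_dataset(images: np.ndarray, labels: np.ndarray,
                    config: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    """Materialise the rotation augmentation for a whole training array;
    originals are kept in front of their rotated copies when
    ``keep_original`` (the upright pose carries the polarisation signal)."""
    xs, ys = [], []
    for img, lbl in zip(images, labels):
        if config.keep_original:
            xs.append(np.asarray(img))
            ys.append(lbl)
        for rot in augment_rotations(img, config):
            xs.append(rot)
            ys.append(lbl)
    return np.stack(xs), np.asarray(ys)


def _xent_forward_backward(state: ClassifierState, x, y):
    logits, cache = state.forward(x)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    state.backward(cache, (g / n).astype(np.float32))
    return float(loss), p


def _prep(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32) / 255.0
    if x.ndim == 3:
        x = x[:, None]
    return x


def train_classifier(train_images, train_labels, val_images, val_labels,
                     config: TrainConfig):
    """Train with per-epoch shuffling and early stopping on validation
    accuracy; returns (best state, history dict)."""
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("empty training or validation split")
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    for lbls in (train_labels, val_labels):
        if lbls.min() < 0 or lbls.max() >= config.n_classes:
            raise ValueError(f"labels outside 0-{config.n_classes - 1}")
    x_train = _prep(train_images)
    x_val = _prep(val_images)
    state = ClassifierState(config)
    opt = Adam(state.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = {"train_loss": [], "val_accuracy": [], "stop_epoch": None}
    best_acc, best_params, since_best = -1.0, None, 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            opt.zero_grad()
            loss, _ = _xent_forward_backward(state, x_train[idx],
                                             train_labels[idx])
            opt.step()
            losses.append(loss)
        val_pred, _ = predict(val_images, state)
        val_acc = float((val_pred == val_labels).mean())
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = [p.data.copy() for p in state.parameters()]
            since_best = 0
        else:
            since_best += 1
        if since_best >= config.patience:
            break
    history["stop_epoch"] = epoch
    if best_params is not None:
        for p, d in zip(state.parameters(), best_params):
            p.data[...] = d
    return state, history


def predict(images, state: ClassifierState,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """(argmax labels, class-probability rows summing to 1)."""
    x = _prep(images)
    probs = []
    for start in range(0, len(x), batch_size):
        logits, _ = state.forward(x[start:start + batch_size])
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs.append(e / e.sum(axis=1, keepdims=True))
    p = np.vstack(probs)
    return p.argmax(axis=1), p


def save_classifier(state: ClassifierState, path: str | Path) -> None:
    payload = {"config": state.config.__dict__,
               "params": [p.data for p in state.parameters()]}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_classifier(path: str | Path) -> ClassifierState:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg = TrainConfig(**payload["config"])
    state = ClassifierState(cfg)
    for p, d in zip(state.parameters(), payload["params"]):
        p.data[...] = d
    return state
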