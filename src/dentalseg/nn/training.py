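"""Training loop: cross-entropy, Adam, scan-disjoint splits, prediction.

Scans (not images) are the unit of data splitting: all projections of
one 3D scan stay in the same split, so test images never show a scan the
model has seen.  The learning-rate ``decay`` is a multiplicative
per-epoch factor applied to the learning rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segnet import SegNet

__all__ = [
    "Adam",
    "ImagePair",
    "TrainConfig",
    "predict",
    "softmax",
    "softmax_cross_entropy",
    "split_by_scan",
    "train",
]


@dataclass
class ImagePair:
    """One training sample: texture image, label image, owning scan."""

    image: np.ndarray  # (C, H, W) float32 in [0, 1]
    labels: np.ndarray  # (H, W) int64 class ids
    scan_id: int | str = 0


@dataclass
class TrainConfig:
    epochs: int = 150
    batch_size: int = 1
    learning_rate: float = 1e-4
    decay: float = 0.995  # multiplicative per-epoch learning-rate factor
    seed: int = 0
    class_weighted: bool = False  # inverse-frequency pixel weighting (off by default)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of (N, C, H, W) logits."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, pixel_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n, c, h, w = logits.shape
    onehot = np.zeros_like(p)
    ni, hi, wi = np.meshgrid(np.arange(n), np.arange(h), np.arange(w), indexing="ij")
    onehot[ni, labels, hi, wi] = 1.0
    eps = 1e-12
    logp = np.log(np.clip((p * onehot).sum(axis=1), eps, None))
    if pixel_weights is None:
        loss = float(-logp.mean())
        grad = (p - onehot) / (n * h * w)
    else:
        wsum = float(pixel_weights.sum())
        loss = float(-(logp * pixel_weights).sum() / wsum)
        grad = (p - onehot) * pixel_weights[:, None] / wsum
    return loss, grad.astype(logits.dtype)


class Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def split_by_scan(pairs, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Split samples into (train, val, test) by scan id.

    Every image of a scan lands in exactly one split; raises if the
    grouping would put a scan in two splits (cannot happen with this
    construction, checked anyway as the training contract).
    """
    pairs = list(pairs)
    scans = sorted({p.scan_id for p in pairs}, key=str)
    rng = np.random.default_rng(seed)
    order = [scans[i] for i in rng.permutation(len(scans))]
    n = len(order)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    groups = (
        set(order[:n_train]),
        set(order[n_train:n_train + n_val]),
        set(order[n_train + n_val:]),
    )
    for a in range(3):
        for b in range(a + 1, 3):
            if groups[a] & groups[b]:
                raise ValueError("a scan appears in two splits")
    return tuple([p for p in pairs if p.scan_id in g] for g in groups)


def _check_disjoint(train_set, val_set) -> None:
    if val_set:
        overlap = {p.scan_id for p in train_set} & {p.scan_id for p in val_set}
        if overlap:
            raise ValueError(f"scans {sorted(map(str, overlap))} appear in two splits")


def _class_weights(pairs, n_classes: int) -> np.ndarray:
    counts = np.zeros(n_classes)
    for p in pairs:
        ids, c = np.unique(p.labels, return_counts=True)
        counts[ids] += c
    w = np.zeros(n_classes)
    present = counts > 0
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w.astype(np.float32)


def train(
    model: SegNet,
    train_set,
    config: TrainConfig,
    val_set=None,
) -> tuple[SegNet, dict]:
    """Cross-entropy training with per-epoch learning-rate decay.

    Returns the trained model (modified in place) and a history dict
    with per-epoch train loss and, when a validation set is given,
    validation loss and mean IoU.  With ``epochs=0`` the weights are
    untouched.  Fully deterministic under a fixed config seed.
    """
    from ..metrics import metrics_2d  # local import to avoid a cycle

    train_set = list(train_set)
    val_set = list(val_set) if val_set else []
    _check_disjoint(train_set, val_set)
    history: dict = {"train_loss": [], "val_loss": [], "val_miou": [], "lr": []}
    if config.epochs == 0:
        return model, history
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.learning_rate)
    weights = (
        _class_weights(train_set, model.config.n_classes)
        if config.class_weighted else None
    )
    lr = config.learning_rate
    for _ in range(config.epochs):
        opt.lr = lr
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            x = np.stack([b.image for b in batch]).astype(np.float32)
            y = np.stack([b.labels for b in batch])
            logits = model.forward(x, train=True)
            pw = weights[y] if weights is not None else None
            loss, grad = softmax_cross_entropy(logits, y, pw)
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
        if val_set:
            vlosses, mious = [], []
            for p in val_set:
                logits = model.forward(p.image[None].astype(np.float32), train=False)
                loss, _ = softmax_cross_entropy(logits, p.labels[None])
                vlosses.append(loss)
                pred = np.argmax(logits[0], axis=0)
                mious.append(metrics_2d(pred, p.labels).mean_iou)
            history["val_loss"].append(float(np.mean(vlosses)))
            history["val_miou"].append(float(np.mean(mious)))
        lr *= config.decay
    return model, history


def predict(model: SegNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class ids for one (C, H, W) image (eval mode)."""
    size = model.config.input_size
    if image.shape[-2:] != (size, size):
        raise ValueError(f"expected a {size}x{size} image, got {image.shape[-2:]}")
    logits = model.forward(image[None].astype(np.float32), train=False)
    return np.argmax(logits[0], axis=0).astype(np.int64)
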