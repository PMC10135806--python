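"""Training: weighted cross-entropy, Adam, early stopping, k-fold CV.

The recipe: batch size 2, Adam (lr 1e-3), weighted categorical
cross-entropy with inverse-frequency class weights, on-the-fly joint
image+mask augmentation, early stopping monitoring a held-out validation
split with patience 25 epochs and restoration of the best-validation
weights.  Evaluation uses 10-fold cross-validation: pixel confusion counts
are pooled over every image when it serves as a test image, then normalized
once globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import augment as aug
from . import nn
from .annotations import LabelMask
from .evaluate import ConfusionMatrix, confusion_from_masks, segmentation_metrics
from .network import NetworkConfig, UNet, labels_from_probabilities
from .preprocess import ImageSample

LOG_FLOOR = 1e-7


@dataclass
class TrainingConfig:
    batch_size: int = 2
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 25            # epochs without validation improvement
    class_weights: str | tuple = "inverse-frequency"
    validation_fraction: float = 0.1
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not isinstance(self.class_weights, str):
            w = np.asarray(self.class_weights, dtype=float)
            if (w <= 0).any():
                raise ValueError("class weights must be strictly positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["class_weights"], str):
            d["class_weights"] = list(map(float, d["class_weights"]))
        return d


@dataclass
class FoldSplit:
    """A k-way partition of image ids; fold sizes differ by at most one."""

    k: int
    folds: list[list]

    def __post_init__(self) -> None:
        flat = [i for f in self.folds for i in f]
        if len(flat) != len(set(flat)):
            raise ValueError("folds are not disjoint")
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes differ by more than one")


def make_folds(image_ids, k: int = 10, seed: int = 0) -> FoldSplit:
    """Seeded shuffle followed by round-robin assignment into k folds."""
    ids = list(image_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} images, got {len(ids)}")
    order = np.random.default_rng(seed).permutation(len(ids))
    folds: list[list] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(ids[idx])
    return FoldSplit(k, folds)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _as_batches(p: np.ndarray, y: np.ndarray):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.ndim == 3:
        p, y = p[None], y[None]
    if p.ndim != 4 or y.ndim != 3 or p.shape[0] != y.shape[0] \
            or p.shape[2:] != y.shape[1:]:
        raise ValueError(f"shape mismatch: probabilities {p.shape}, "
                         f"labels {y.shape}")
    return p, y


def weighted_categorical_cross_entropy(p: np.ndarray, y: np.ndarray | LabelMask,
                                       w) -> float:
    """Mean over pixels of ``-w[y] * log(max(p_y, 1e-7))``.

    ``p`` is (n_classes, H, W) or (N, n_classes, H, W); ``y`` the integer
    label mask(s); ``w`` strictly positive per-class weights.
    """
    if isinstance(y, LabelMask):
        y = y.grid
    w = np.asarray(w, dtype=np.float64)
    if (w <= 0).any():
        raise ValueError("class weights must be strictly positive")
    p, y = _as_batches(p, np.asarray(y))
    if len(w) != p.shape[1]:
        raise ValueError(f"{len(w)} weights for {p.shape[1]} classes")
    p_true = np.take_along_axis(p, y[:, None].astype(np.int64), axis=1)[:, 0]
    return float(np.mean(-w[y] * np.log(np.maximum(p_true, LOG_FLOOR))))


def _loss_and_grad(logits: np.ndarray, y: np.ndarray, w: np.ndarray
                   ) -> tuple[float, np.ndarray]:
    """Loss plus its gradient with respect to the logits (softmax fused)."""
    p = nn.softmax_channels(logits.astype(np.float64))
    loss = weighted_categorical_cross_entropy(p, y, w)
    n, k, h, wd = p.shape
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, y[:, None].astype(np.int64), 1.0, axis=1)
    pix_w = w[y][:, None]                       # (N, 1, H, W)
    grad = pix_w * (p - onehot) / (n * h * wd)
    return loss, grad.astype(nn.DTYPE)


def compute_class_weights(masks, n_classes: int = 3) -> np.ndarray:
    """Inverse pixel-frequency weights over training masks, rescaled so the
    weights average to 1.  Errors if a class never occurs."""
    masks = list(masks)
    if not masks:
        raise ValueError("empty mask list")
    counts = np.zeros(n_classes, dtype=np.int64)
    for m in masks:
        grid = m.grid if isinstance(m, LabelMask) else np.asarray(m)
        counts += np.bincount(grid.ravel(), minlength=n_classes)[:n_classes]
    if (counts == 0).any():
        from .evaluate import CLASS_NAMES

        missing = [CLASS_NAMES[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(
            f"class(es) absent from training masks: {', '.join(missing)}"
        )
    inv = counts.sum() / counts.astype(np.float64)
    return inv / inv.mean()


# ---------------------------------------------------------------------------
# Early stopping
# ---------------------------------------------------------------------------

class EarlyStopping:
    """Stop after ``patience`` epochs without validation improvement and
    remember the best weights seen."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_loss = np.inf
        self.best_weights: list[np.ndarray] | None = None
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, val_loss: float, weights: list[np.ndarray],
               epoch: int) -> bool:
        """Record an epoch result; returns True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_weights = [w.copy() for w in weights]
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


@dataclass
class TrainingLog:
    history: pd.DataFrame            # epoch, train_loss, val_loss
    seed: int
    config: dict
    net_config: dict
    class_weights: list[float]
    best_epoch: int
    stopped_early: bool


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _stack(samples: list[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples])[:, None]
    labels = np.stack([s.mask.grid for s in samples])
    return images.astype(nn.DTYPE), labels


def train_model(train_samples: list[ImageSample],
                config: TrainingConfig | None = None,
                net_config: NetworkConfig | None = None,
                ) -> tuple[UNet, TrainingLog]:
    """Train a U-Net on image+mask samples.

    A ``validation_fraction`` of the samples (at least one) is held out to
    monitor early stopping; the rest are batched and augmented on the fly.
    Returns the network with the best-validation weights restored, plus a
    log of per-epoch losses.
    """
    config = config or TrainingConfig()
    net_config = net_config or NetworkConfig()
    samples = list(train_samples)
    if any(s.mask is None for s in samples):
        raise ValueError("every training sample needs a mask")
    n_val = max(1, int(round(config.validation_fraction * len(samples))))
    if len(samples) - n_val < 2:
        raise ValueError(
            f"need >= 2 training images after holding out {n_val} for "
            f"validation; got {len(samples)} total"
        )

    ss = np.random.SeedSequence(config.seed)
    s_split, s_net, s_shuffle, s_aug = (
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)
    )
    perm = np.random.default_rng(s_split).permutation(len(samples))
    val = [samples[i] for i in perm[:n_val]]
    train = [samples[i] for i in perm[n_val:]]

    if isinstance(config.class_weights, str):
        if config.class_weights != "inverse-frequency":
            raise ValueError(f"unknown class_weights {config.class_weights!r}")
        weights = compute_class_weights([s.mask for s in train])
    else:
        weights = np.asarray(config.class_weights, dtype=np.float64)

    net = UNet(net_config, seed=s_net)
    optim = nn.Adam(net.parameters(), net.gradients(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(s_shuffle)
    aug_rng = np.random.default_rng(s_aug)
    stopper = EarlyStopping(config.patience)
    x_val, y_val = _stack(val)

    rows = []
    stopped = False
    for epoch in range(1, config.max_epochs + 1):
        order = shuffle_rng.permutation(len(train))
        batch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train[i] for i in order[start:start + config.batch_size]]
            if config.augment:
                batch = [aug.augment(s, aug_rng) for s in batch]
            x, y = _stack(batch)
            logits = net.forward(x, training=True)
            loss, dlogits = _loss_and_grad(logits, y, weights)
            net.backward(dlogits)
            optim.step()
            batch_losses.append(loss)
        val_losses = []
        for i in range(len(val)):
            logits = net.forward(x_val[i:i + 1], training=False)
            p = nn.softmax_channels(logits.astype(np.float64))
            val_losses.append(
                weighted_categorical_cross_entropy(p, y_val[i:i + 1], weights)
            )
        train_loss = float(np.mean(batch_losses))
        val_loss = float(np.mean(val_losses))
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss})
        if stopper.update(val_loss, net.parameters(), epoch):
            stopped = True
            break
    if stopper.best_weights is not None:
        net.set_weights(stopper.best_weights)
    log = TrainingLog(
        history=pd.DataFrame(rows), seed=config.seed,
        config=config.to_dict(), net_config=net_config.to_dict(),
        class_weights=list(map(float, weights)),
        best_epoch=stopper.best_epoch, stopped_early=stopped,
    )
    return net, log


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    confusion: ConfusionMatrix              # pooled pixel counts
    normalized: ConfusionMatrix             # counts / total, sums to 1
    per_fold: list[dict] = field(default_factory=list)
    folds: FoldSplit | None = None

    @property
    def metrics(self):
        return segmentation_metrics(self.confusion)


def cross_validate(samples: list[ImageSample], k: int = 10,
                   net_config: NetworkConfig | None = None,
                   train_config: TrainingConfig | None = None,
                   seed: int = 0,
                   predict_fn=None) -> CVResult:
    """k-fold cross-validation with globally pooled confusion counts.

    Each fold is held out once; a fresh network is trained on the remaining
    folds (per-fold seeds derived deterministically from ``seed``) and
    predicts the held-out images.  Pixel confusion counts accumulate over
    ALL held-out predictions and are normalized once at the end, so the
    result is permutation-invariant in fold order.

    ``predict_fn(train_samples, test_samples, fold_seed) -> list[LabelMask]``
    substitutes the train+predict step when given (e.g. an oracle predictor
    in tests).
    """
    samples = list(samples)
    by_id = {s.sample_id: s for s in samples}
    if len(by_id) != len(samples):
        raise ValueError("sample_ids must be unique")
    folds = make_folds(list(by_id), k=k, seed=seed)
    fold_seeds = [
        int(c.generate_state(1)[0] % (2 ** 31))
        for c in np.random.SeedSequence(seed).spawn(k)
    ]
    net_config = net_config or NetworkConfig()
    train_config = train_config or TrainingConfig()

    counts = np.zeros((3, 3), dtype=np.int64)
    per_fold = []
    for f, test_ids in enumerate(folds.folds):
        test = [by_id[i] for i in test_ids]
        train = [s for s in samples if s.sample_id not in set(test_ids)]
        if predict_fn is not None:
            preds = predict_fn(train, test, fold_seeds[f])
        else:
            from dataclasses import replace

            cfg = replace(train_config, seed=fold_seeds[f])
            net, _ = train_model(train, cfg, net_config)
            from .network import predict as _predict

            preds = [labels_from_probabilities(_predict(net, s.image))
                     for s in test]
        cm = confusion_from_masks([s.mask for s in test], preds)
        counts += cm.counts.astype(np.int64)
        per_fold.append({
            "fold": f, "test_ids": list(test_ids),
            "confusion": cm.counts.tolist(),
            "mean_dice": segmentation_metrics(cm).mean_dice
            if cm.total else float("nan"),
        })
    pooled = ConfusionMatrix(counts)
    return CVResult(pooled, pooled.normalize(), per_fold, folds)
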