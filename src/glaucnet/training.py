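"""Training and evaluation of the multi-task network.

The procedure mirrors standard supervised practice for joint
segmentation+classification: stratified train/validation/test split,
mini-batch training with SGD or Adam under the epoch-scheduled FC loss for
the classification head plus a soft-Dice loss for the segmentation head,
per-epoch validation accuracy in evaluation mode, and a final test-set
metrics report (confusion matrix, sensitivity/specificity, ROC/AUC, Dice).

Everything is a pure function of the configuration, including its seed:
identical configs reproduce identical histories bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import losses as L
from . import phantom as ph
from .losses import LossConfig
from .metrics import MetricsReport, confusion, dice, roc_auc, scalar_metrics
from .network import MTLNet, NetworkSpec, SEG_CLASSES, build_network
from ._nn import make_optimizer

logger = logging.getLogger("glaucnet")

_DICE_EPS = 1e-6


@dataclass
class TrainConfig:
    """Optimization settings: optimizer (sgd/adam), learning rate, batch
    size B, epoch count M, the loss hyperparameters, the weight of the
    segmentation loss in the total, and the split fractions."""

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 30
    loss: LossConfig = None
    seg_weight: float = 1.0
    split: tuple = (0.70, 0.15, 0.15)
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")
        if self.seg_weight < 0:
            raise ValueError("seg_weight must be >= 0")
        self.split = tuple(float(f) for f in self.split)
        if len(self.split) != 3 or any(f <= 0 for f in self.split):
            raise ValueError("split must be three positive fractions")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(self.split)}")
        if self.loss is None:
            self.loss = LossConfig(total_epochs=self.epochs,
                                   switch_epoch=self.epochs // 2)
        elif isinstance(self.loss, dict):
            self.loss = LossConfig.from_dict(self.loss)
        if self.loss.total_epochs != self.epochs:
            raise ValueError(
                f"loss.total_epochs ({self.loss.total_epochs}) must equal "
                f"epochs ({self.epochs})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split"] = list(self.split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["split"] = tuple(d["split"])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch training record plus the final test report."""

    train_loss: list = field(default_factory=list)
    active_loss: list = field(default_factory=list)  # "focal" | "correntropy"
    val_accuracy: list = field(default_factory=list)
    test_report: MetricsReport | None = None

    def to_dict(self) -> dict:
        return {
            "train_loss": [float(v) for v in self.train_loss],
            "active_loss": list(self.active_loss),
            "val_accuracy": [float(v) for v in self.val_accuracy],
            "test_report": self.test_report.to_dict() if self.test_report else None,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


# ------------------------------------------------------------------ splitting


def _largest_remainder(n: int, fracs) -> list[int]:
    raw = [n * f for f in fracs]
    out = [int(np.floor(r)) for r in raw]
    remainders = sorted(range(len(fracs)), key=lambda i: (-(raw[i] - out[i]), i))
    for i in remainders[: n - sum(out)]:
        out[i] += 1
    return out


def split_dataset(dataset, cfg: TrainConfig):
    """Stratified, exact, deterministic train/validation/test partition.

    Split sizes follow the configured fractions exactly (largest-remainder
    rounding); within each split, class proportions stay within one sample
    of the global proportions. Raises if any class would be absent from a
    split.
    """
    if len(dataset) < 10:
        raise ValueError("dataset must contain at least 10 samples")
    labels = np.asarray(dataset.labels)
    classes = np.unique(labels)
    sizes = _largest_remainder(len(dataset), cfg.split)

    quotas = {c: _largest_remainder(int(np.sum(labels == c)), cfg.split)
              for c in classes}
    col = [sum(quotas[c][s] for c in classes) for s in range(3)]
    # reconcile per-class quotas with the exact split totals
    while col != sizes:
        s_over = next(s for s in range(3) if col[s] > sizes[s])
        s_under = next(s for s in range(3) if col[s] < sizes[s])
        c_move = max(classes, key=lambda c: (quotas[c][s_over], c))
        quotas[c_move][s_over] -= 1
        quotas[c_move][s_under] += 1
        col = [sum(quotas[c][s] for c in classes) for s in range(3)]
    for c in classes:
        if any(q == 0 for q in quotas[c]):
            raise ValueError(
                f"class {c} would be absent from a split at fractions {cfg.split}"
            )

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    parts = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        a, b = quotas[c][0], quotas[c][0] + quotas[c][1]
        parts[0] += idx[:a].tolist()
        parts[1] += idx[a:b].tolist()
        parts[2] += idx[b:].tolist()
    return tuple(dataset.subset(sorted(p)) for p in parts)


# ----------------------------------------------------------------- internals


def _batch_arrays(samples):
    images = np.stack([s.image for s in samples]).astype(np.float32, copy=False)
    masks = np.stack([s.mask for s in samples])
    labels = np.array([s.label for s in samples], dtype=np.int64)
    return images, masks, labels


def _soft_dice(seg_probs: np.ndarray, masks: np.ndarray):
    """Per-batch soft-Dice loss over the 3 mask classes and its gradient
    with respect to the per-pixel class probabilities."""
    b = seg_probs.shape[0]
    onehot = np.stack([(masks == c) for c in range(SEG_CLASSES)], axis=-1)
    onehot = onehot.astype(np.float32)
    axes = tuple(range(1, seg_probs.ndim - 1))
    inter = (seg_probs * onehot).sum(axis=axes)          # (B, C)
    psum = seg_probs.sum(axis=axes)
    tsum = onehot.sum(axis=axes)
    num = 2.0 * inter + _DICE_EPS
    den = psum + tsum + _DICE_EPS
    dice_cs = num / den
    loss = 1.0 - float(dice_cs.mean())
    # d(dice)/dp = (2 t * den - num) / den^2 ; loss averages over B*C terms
    sh = (b,) + (1,) * len(axes) + (SEG_CLASSES,)
    grad = -(2.0 * onehot * den.reshape(sh) - num.reshape(sh)) / (den**2).reshape(sh)
    grad /= b * SEG_CLASSES
    return loss, grad.astype(np.float32)


def _softmax_backward(probs: np.ndarray, dprobs: np.ndarray,
                      axis: int = -1) -> np.ndarray:
    dot = (dprobs * probs).sum(axis=axis, keepdims=True)
    return (probs * (dprobs - dot)).astype(np.float32)


def predict(net: MTLNet, images: np.ndarray, batch_size: int = 32):
    """Evaluation-mode forward over (N, H, W, 3) images; returns
    (seg label maps (N, H, W), class probabilities (N, 2))."""
    images = np.asarray(images, dtype=np.float32)
    segs, probs = [], []
    for i in range(0, len(images), batch_size):
        out = net.forward(images[i:i + batch_size], training=False)
        segs.append(out.seg_map.argmax(axis=-1).astype(np.uint8))
        probs.append(out.cls_probs)
    return np.concatenate(segs), np.concatenate(probs)


def evaluate(net: MTLNet, dataset, batch_size: int = 32,
             use_clean_labels: bool = False) -> MetricsReport:
    """Full metric suite on a dataset in evaluation mode.

    ``use_clean_labels`` scores against the pre-flip labels, isolating
    model quality from injected label noise; masks are always clean.
    """
    seg_maps, cls_probs = predict(net, dataset.images, batch_size)
    labels = dataset.clean_labels if use_clean_labels else dataset.labels
    scores = cls_probs[:, 1]
    preds = (scores >= 0.5).astype(int)
    cm = confusion(labels, preds)
    accuracy, sensitivity, specificity, precision, f1 = scalar_metrics(cm)
    roc_points, auc = roc_auc(labels, scores)
    masks = dataset.masks
    dice_disc = float(np.mean([dice(s, m, ph.DISC) for s, m in zip(seg_maps, masks)]))
    dice_cup = float(np.mean([dice(s, m, ph.CUP) for s, m in zip(seg_maps, masks)]))
    return MetricsReport(
        accuracy=accuracy, sensitivity=sensitivity, specificity=specificity,
        precision=precision, f1=f1, auc=auc, roc_points=roc_points,
        dice_disc=dice_disc, dice_cup=dice_cup, confusion=cm,
    )


# -------------------------------------------------------------------- training


def train(net: MTLNet, datasets, cfg: TrainConfig):
    """Train the network on (train, val, test) datasets.

    Per epoch: mini-batches with on-the-fly augmentation (training split
    only), total loss = FC classification loss + seg_weight * soft-Dice
    segmentation loss, one optimizer step per batch, then validation
    accuracy in evaluation mode. Finishes with a test-set metrics report.
    Returns ``(net, TrainHistory)``.
    """
    train_ds, val_ds, test_ds = datasets
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
    opt = make_optimizer(cfg.optimizer, net.params(), cfg.learning_rate)
    history = TrainHistory()
    n = len(train_ds)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_seen = 0.0, 0
        for b0 in range(0, n, cfg.batch_size):
            batch_idx = order[b0:b0 + cfg.batch_size]
            samples = [train_ds[int(i)] for i in batch_idx]
            if cfg.augment:
                samples = [ph.augment(s, rng) for s in samples]
            images, masks, labels = _batch_arrays(samples)

            out = net.forward(images, training=True, rng=rng)
            p1 = out.cls_probs[:, 1].astype(np.float64)
            bsz = len(samples)

            cls_loss = L.batch_loss(p1, labels, epoch, cfg.loss)
            g_p1 = L.fc_loss_grad(p1, labels, epoch, cfg.loss) / bsz
            d_cls = np.zeros_like(out.cls_probs)
            d_cls[:, 1] = g_p1 * p1 * (1.0 - p1)
            d_cls[:, 0] = -d_cls[:, 1]

            seg_loss, d_seg_probs = _soft_dice(out.seg_map, masks)
            d_seg = _softmax_backward(out.seg_map, cfg.seg_weight * d_seg_probs)

            total = cls_loss + cfg.seg_weight * seg_loss
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}"
                )
            opt.zero_grad()
            net.backward(d_seg, d_cls)
            opt.step()
            epoch_loss += total * bsz
            n_seen += bsz

        _, val_probs = predict(net, val_ds.images, cfg.batch_size)
        val_acc = float(np.mean((val_probs[:, 1] >= 0.5).astype(int) == val_ds.labels))
        flag = "focal" if epoch < cfg.loss.switch_epoch else "correntropy"
        history.train_loss.append(epoch_loss / n_seen)
        history.active_loss.append(flag)
        history.val_accuracy.append(val_acc)
        logger.info("epoch %3d [%s] train_loss=%.4f val_acc=%.3f",
                    epoch, flag, epoch_loss / n_seen, val_acc)

    history.test_report = evaluate(net, test_ds, cfg.batch_size)
    return net, history


# ------------------------------------------------------------ end-to-end runs


def run_phantom_experiment(
    loss: str = "fc",
    seed: int = 0,
    n_images: int = 600,
    image_size: int = 64,
    glaucoma_fraction: float = 1 / 6,
    label_flip_rate: float = 0.05,
    noise_sd: float = 0.05,
    base_channels: int = 8,
    epochs: int = 30,
    switch_epoch: int | None = None,
    optimizer: str = "adam",
    learning_rate: float = 1e-3,
    batch_size: int = 16,
    seg_weight: float = 1.0,
):
    """Generate a phantom dataset, train the 2-D multi-task network, and
    score the held-out test split against the clean labels and masks.

    ``loss`` selects the classification loss: ``"fc"`` (focal switching to
    correntropy at ``switch_epoch``, default M/2) or ``"cross_entropy"``
    (plain cross-entropy throughout, the robustness baseline). Returns a
    dict with the trained net, datasets, history, and the clean-label test
    metrics.
    """
    if switch_epoch is None:
        switch_epoch = epochs // 2
    if loss == "fc":
        loss_cfg = LossConfig(switch_epoch=switch_epoch, total_epochs=epochs)
    elif loss == "cross_entropy":
        loss_cfg = LossConfig(gamma=0.0, theta=1.0, class_balanced=False,
                              switch_epoch=epochs, total_epochs=epochs)
    else:
        raise ValueError(f"loss must be 'fc' or 'cross_entropy', got {loss!r}")

    pcfg = ph.PhantomConfig(
        n_images=n_images, image_size=image_size,
        glaucoma_fraction=glaucoma_fraction, label_flip_rate=label_flip_rate,
        noise_sd=noise_sd, seed=seed,
    )
    dataset = ph.generate_dataset(pcfg)
    tcfg = TrainConfig(optimizer=optimizer, learning_rate=learning_rate,
                       batch_size=batch_size, epochs=epochs, loss=loss_cfg,
                       seg_weight=seg_weight, seed=seed)
    splits = split_dataset(dataset, tcfg)
    spec = NetworkSpec(input_size=image_size, base_channels=base_channels)
    net = build_network(spec, seed=seed)
    net, history = train(net, splits, tcfg)
    clean_report = evaluate(net, splits[2], use_clean_labels=True)
    return {
        "net": net, "history": history, "splits": splits,
        "clean_report": clean_report, "train_config": tcfg, "phantom_config": pcfg,
    }
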