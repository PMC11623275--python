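"""Scikit-learn-style estimator wrapping the multi-task network.

:class:`GlaucomaScreener` exposes the whole pipeline — network
construction, FC-loss training schedule, and evaluation-mode inference —
through the familiar ``fit`` / ``predict`` / ``predict_proba`` interface,
so it composes with sklearn model selection and pipelines. ``X`` is an
array of ONH crops ``(n, size, size, 3)`` with intensities in [0, 1];
``y`` the binary glaucoma labels; disc/cup masks are an optional ``fit``
argument enabling the segmentation task (without them the model trains
classification-only).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .losses import LossConfig
from .network import NetworkSpec, build_network
from .phantom import PhantomDataset, Sample
from .training import TrainConfig, predict as _predict, split_dataset, train as _train


class GlaucomaScreener(BaseEstimator, ClassifierMixin):
    """Joint disc/cup segmentation and glaucoma classification.

    Parameters mirror the architecture spec (``base_channels``,
    ``fusion_stages``, ``fc_hidden``, ``dropout_rate``), the optimizer
    (``optimizer``, ``learning_rate``, ``batch_size``, ``epochs``), and the
    FC loss (``gamma``, ``theta``, ``beta``, ``switch_epoch``,
    ``class_balanced``). ``loss="cross_entropy"`` disables both the focal
    weighting and the correntropy switch, giving the plain cross-entropy
    baseline. ``val_fraction`` of the fitting data is carved out
    (stratified) for the per-epoch validation accuracy.

    Fitted attributes: ``net_`` (the trained network), ``history_``
    (per-epoch record), ``classes_``.
    """

    def __init__(
        self,
        image_size: int = 64,
        base_channels: int = 8,
        fusion_stages: tuple = (3, 4, 5),
        fc_hidden: int = 256,
        dropout_rate: float = 0.5,
        loss: str = "fc",
        gamma: float = 2.0,
        theta: float = 0.25,
        beta: float = 1.0,
        switch_epoch: int | None = None,
        class_balanced: bool = True,
        kernel_denominator: str = "beta_sq",
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        epochs: int = 30,
        seg_weight: float = 1.0,
        val_fraction: float = 0.15,
        augment: bool = True,
        seed: int = 0,
    ):
        self.image_size = image_size
        self.base_channels = base_channels
        self.fusion_stages = fusion_stages
        self.fc_hidden = fc_hidden
        self.dropout_rate = dropout_rate
        self.loss = loss
        self.gamma = gamma
        self.theta = theta
        self.beta = beta
        self.switch_epoch = switch_epoch
        self.class_balanced = class_balanced
        self.kernel_denominator = kernel_denominator
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seg_weight = seg_weight
        self.val_fraction = val_fraction
        self.augment = augment
        self.seed = seed

    # ------------------------------------------------------------ internals

    def _loss_config(self) -> LossConfig:
        if self.loss == "cross_entropy":
            return LossConfig(gamma=0.0, theta=1.0, class_balanced=False,
                              switch_epoch=self.epochs, total_epochs=self.epochs)
        if self.loss != "fc":
            raise ValueError(f"loss must be 'fc' or 'cross_entropy', got {self.loss!r}")
        switch = self.epochs // 2 if self.switch_epoch is None else self.switch_epoch
        return LossConfig(gamma=self.gamma, theta=self.theta, beta=self.beta,
                          switch_epoch=switch, total_epochs=self.epochs,
                          class_balanced=self.class_balanced,
                          kernel_denominator=self.kernel_denominator)

    def _as_dataset(self, X, y, masks) -> PhantomDataset:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[1] != X.shape[2] or X.shape[3] != 3:
            raise ValueError(f"X must have shape (n, size, size, 3), got {X.shape}")
        y = np.asarray(y)
        if masks is None:
            masks = np.zeros(X.shape[:3], dtype=np.uint8)
            seg_weight = 0.0
        else:
            masks = np.asarray(masks, dtype=np.uint8)
            seg_weight = self.seg_weight
        samples = [
            Sample(image=x, mask=m, label=int(l), true_cdr=0.5, clean_label=int(l))
            for x, m, l in zip(X, masks, y)
        ]
        return PhantomDataset(samples), seg_weight

    # ------------------------------------------------------------ sklearn API

    def fit(self, X, y, masks=None, validation_data=None):
        """Train on images ``X`` and labels ``y`` (optionally with masks).

        ``validation_data=(X_val, y_val)`` supplies an explicit validation
        set; otherwise ``val_fraction`` is carved out of ``(X, y)``.
        """
        dataset, seg_weight = self._as_dataset(X, y, masks)
        self.classes_ = np.unique(np.asarray(y))
        tcfg = TrainConfig(
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            batch_size=self.batch_size, epochs=self.epochs,
            loss=self._loss_config(), seg_weight=seg_weight,
            augment=self.augment, seed=self.seed,
            split=(1 - 2 * self.val_fraction, self.val_fraction, self.val_fraction),
        )
        if validation_data is not None:
            val_ds, _ = self._as_dataset(*validation_data, None)
            train_ds, val_split = dataset, val_ds
        else:
            # reuse the stratified splitter; fold the spare slice back into train
            part_train, part_val, part_rest = split_dataset(dataset, tcfg)
            train_ds = PhantomDataset(part_train.samples + part_rest.samples)
            val_split = part_val
        spec = NetworkSpec(
            input_size=self.image_size, base_channels=self.base_channels,
            fusion_stages=tuple(self.fusion_stages), fc_hidden=self.fc_hidden,
            dropout_rate=self.dropout_rate,
        )
        net = build_network(spec, seed=self.seed)
        # test split is unused during fitting; validation doubles as placeholder
        self.net_, self.history_ = _train(net, (train_ds, val_split, val_split), tcfg)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        _, probs = _predict(self.net_, X, self.batch_size)
        return probs

    def predict(self, X):
        return self.predict_proba(X).argmax(axis=1)

    def predict_segmentation(self, X):
        """Per-pixel {background, disc, cup} label maps."""
        check_is_fitted(self, "net_")
        segs, _ = _predict(self.net_, np.asarray(X, dtype=np.float32),
                           self.batch_size)
        return segs
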