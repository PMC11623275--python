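"""Classification losses for glaucoma screening: cross-entropy, focal,
correntropy-induced, and the FC mixed loss.

The FC loss is an epoch-scheduled mixture: the first ``switch_epoch`` epochs
use the focal loss, which concentrates the gradient on hard examples and
re-weights the minority (glaucoma) class; the remaining epochs use the
correntropy-induced loss (CL loss), a bounded Gaussian-kernel loss that is
insensitive to outliers such as mislabelled images. Intuition: focal loss
drives the model to fit the hard minority cases early on; the CL loss then
refines the fit while refusing to chase samples whose error stays large
(label noise), because its per-sample loss saturates at 1.

All functions are vectorised over numpy arrays and also accept scalars.
Probabilities refer to the positive (glaucoma) class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "LossConfig",
    "clip_probability",
    "cross_entropy",
    "aggregate_prob",
    "focal_loss",
    "correntropy_loss",
    "fc_loss",
    "fc_loss_grad",
    "batch_loss",
]

#: probabilities are clipped to [EPS, 1-EPS] before any logarithm
EPS = 1e-7


@dataclass
class LossConfig:
    """Hyperparameters of the FC mixed loss family.

    Parameters
    ----------
    gamma : float
        Focusing parameter of the focal loss (>= 0). Larger values
        down-weight well-classified samples more strongly. 0 recovers
        plain cross-entropy (with ``theta=1``, ``class_balanced=False``).
    theta : float
        Class-weighting factor in (0, 1]. With ``class_balanced`` on,
        positives are weighted by ``theta`` and negatives by ``1 - theta``;
        off, every sample is scaled by ``theta``.
    beta : float
        Gaussian-kernel bandwidth of the correntropy loss (> 0), in units
        of label-probability error.
    switch_epoch : int
        Epoch at which training switches from focal to correntropy loss.
        Epochs ``< switch_epoch`` use focal loss, the rest correntropy.
    total_epochs : int
        Total number of training epochs M; ``0 <= switch_epoch <= total_epochs``.
    class_balanced : bool
        Whether ``theta`` is applied asymmetrically per class (default) or
        as a uniform scale factor.
    kernel_denominator : str
        ``"beta_sq"`` uses exp(-e^2/beta^2); ``"two_beta_sq"`` the standard
        Gaussian-kernel convention exp(-e^2/(2 beta^2)).
    """

    gamma: float = 2.0
    theta: float = 0.25
    beta: float = 1.0
    switch_epoch: int = 15
    total_epochs: int = 30
    class_balanced: bool = True
    kernel_denominator: str = "beta_sq"

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if not (0 < self.theta <= 1):
            raise ValueError(f"theta must be in (0, 1], got {self.theta}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.total_epochs <= 0:
            raise ValueError(f"total_epochs must be > 0, got {self.total_epochs}")
        if not (0 <= self.switch_epoch <= self.total_epochs):
            raise ValueError(
                f"switch_epoch must be in [0, total_epochs={self.total_epochs}], "
                f"got {self.switch_epoch}"
            )
        if self.kernel_denominator not in ("beta_sq", "two_beta_sq"):
            raise ValueError(
                f"kernel_denominator must be 'beta_sq' or 'two_beta_sq', "
                f"got {self.kernel_denominator!r}"
            )

    @property
    def kernel_d(self) -> float:
        """The denominator D of the correntropy exponent exp(-e^2/D)."""
        d = self.beta**2
        return 2.0 * d if self.kernel_denominator == "two_beta_sq" else d

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(**d)


def _validate(predicted, actual):
    predicted = np.asarray(predicted, dtype=np.float64)
    actual = np.asarray(actual)
    if np.any(predicted < 0) or np.any(predicted > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.all(np.isin(actual, (0, 1))):
        raise ValueError("actual labels must be 0 or 1")
    return predicted, actual.astype(np.float64)


def clip_probability(predicted):
    """Clip probabilities to the open interval (0, 1) via [EPS, 1-EPS]."""
    return np.clip(predicted, EPS, 1.0 - EPS)


def cross_entropy(predicted, actual):
    """Binary cross-entropy -a*log(p) - (1-a)*log(1-p), natural log.

    Probabilities exactly 0 or 1 are clipped, never producing infinities.
    """
    predicted, actual = _validate(predicted, actual)
    p = clip_probability(predicted)
    return -(actual * np.log(p) + (1.0 - actual) * np.log1p(-p))


def aggregate_prob(predicted, actual):
    """Probability assigned to the *true* class: p if a=1 else 1-p.

    ``cross_entropy(p, a) == -log(aggregate_prob(p, a))`` after clipping.
    """
    predicted, actual = _validate(predicted, actual)
    return np.where(actual == 1, predicted, 1.0 - predicted)


def _focal_weight(actual, cfg: LossConfig):
    if cfg.class_balanced:
        return np.where(actual == 1, cfg.theta, 1.0 - cfg.theta)
    return np.full_like(np.asarray(actual, dtype=np.float64), cfg.theta)


def focal_loss(predicted, actual, cfg: LossConfig):
    """Class-weighted focal loss w * (1-m)^gamma * (-log m).

    m is the aggregated true-class probability; w is theta for positives
    and 1-theta for negatives when ``class_balanced`` is on, theta uniformly
    otherwise. gamma=0, theta=1, class_balanced off recovers cross-entropy.
    """
    predicted, actual = _validate(predicted, actual)
    m = clip_probability(aggregate_prob(predicted, actual))
    w = _focal_weight(actual, cfg)
    return w * np.power(1.0 - m, cfg.gamma) * (-np.log(m))


def correntropy_loss(predicted, actual, cfg: LossConfig):
    """Correntropy-induced loss 1 - exp(-e^2/D), e = a - p.

    Bounded in [0, 1), strictly increasing in |e|, approximately e^2/D for
    small errors and saturating for large ones — which is what makes it
    robust to outliers and label noise.
    """
    predicted, actual = _validate(predicted, actual)
    e = actual - predicted
    # expm1 keeps full precision near zero error
    return -np.expm1(-(e**2) / cfg.kernel_d)


def fc_loss(predicted, actual, epoch: int, cfg: LossConfig):
    """The epoch-scheduled mixed loss: focal before ``switch_epoch``,
    correntropy-induced from ``switch_epoch`` on. The switch is hard.
    """
    if not (0 <= epoch < cfg.total_epochs):
        raise ValueError(
            f"epoch must be in [0, total_epochs={cfg.total_epochs}), got {epoch}"
        )
    if epoch < cfg.switch_epoch:
        return focal_loss(predicted, actual, cfg)
    return correntropy_loss(predicted, actual, cfg)


def fc_loss_grad(predicted, actual, epoch: int, cfg: LossConfig):
    """d(fc_loss)/d(predicted), elementwise; used by the training loop.

    The gradient is evaluated at the clipped probability, matching the
    forward computation.
    """
    if not (0 <= epoch < cfg.total_epochs):
        raise ValueError(
            f"epoch must be in [0, total_epochs={cfg.total_epochs}), got {epoch}"
        )
    predicted, actual = _validate(predicted, actual)
    if epoch < cfg.switch_epoch:
        m = clip_probability(aggregate_prob(predicted, actual))
        w = _focal_weight(actual, cfg)
        one_m = 1.0 - m
        # dL/dm = w * [gamma (1-m)^(g-1) log m - (1-m)^g / m]
        if cfg.gamma == 0:
            dl_dm = -w / m
        else:
            dl_dm = w * (
                cfg.gamma * np.power(one_m, cfg.gamma - 1.0) * np.log(m)
                - np.power(one_m, cfg.gamma) / m
            )
        dm_dp = np.where(actual == 1, 1.0, -1.0)
        return dl_dm * dm_dp
    e = actual - predicted
    d = cfg.kernel_d
    # dL/de = (2e/D) exp(-e^2/D); de/dp = -1
    return -(2.0 * e / d) * np.exp(-(e**2) / d)


def batch_loss(predicted, actual, epoch: int, cfg: LossConfig) -> float:
    """Arithmetic mean of per-sample FC losses over a non-empty batch."""
    predicted = np.atleast_1d(np.asarray(predicted, dtype=np.float64))
    actual = np.atleast_1d(np.asarray(actual))
    if predicted.size == 0:
        raise ValueError("batch must be non-empty")
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same length")
    return float(np.mean(fc_loss(predicted, actual, epoch, cfg)))
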