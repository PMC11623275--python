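"""SGD and Adam optimizers over lists of :class:`Param`."""

from __future__ import annotations

import numpy as np

from .layers import F32, Param


class Optimizer:
    def __init__(self, params: list[Param], lr: float):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= F32(self.momentum)
            v += p.grad
            p.value -= F32(self.lr) * v


class Adam(Optimizer):
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self._t
        bc2 = 1 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= F32(b1)
            m += F32(1 - b1) * p.grad
            v *= F32(b2)
            v += F32(1 - b2) * p.grad * p.grad
            p.value -= F32(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + F32(self.eps))


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    name = name.lower()
    if name == "sgd":
        return SGD(params, lr)
    if name == "adam":
        return Adam(params, lr)
    raise ValueError(f"unknown optimizer {name!r}; expected 'sgd' or 'adam'")
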