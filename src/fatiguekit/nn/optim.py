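"""First-order optimizers operating on ``Param`` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Optimizer:
    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr: float, momentum: float = 0.0):
        super().__init__(params, lr)
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


class RMSProp(Optimizer):
    def __init__(self, params, lr: float, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self._s = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, s in zip(self.params, self._s):
            s *= self.rho
            s += (1 - self.rho) * p.grad ** 2
            p.value -= self.lr * p.grad / (np.sqrt(s) + self.eps)


class Adadelta(Optimizer):
    """Adadelta with a learning-rate multiplier on the adaptive step."""

    def __init__(self, params, lr: float = 1.0, rho: float = 0.95,
                 eps: float = 1e-6):
        super().__init__(params, lr)
        self.rho = rho
        self.eps = eps
        self._sg = [np.zeros_like(p.value) for p in params]
        self._sd = [np.zeros_like(p.value) for p in params]

    def step(self):
        for p, sg, sd in zip(self.params, self._sg, self._sd):
            sg *= self.rho
            sg += (1 - self.rho) * p.grad ** 2
            delta = (np.sqrt(sd + self.eps) / np.sqrt(sg + self.eps)) * p.grad
            sd *= self.rho
            sd += (1 - self.rho) * delta ** 2
            p.value -= self.lr * delta


class Adam(Optimizer):
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self._t)
            vhat = v / (1 - b2 ** self._t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._u = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self):
        self._t += 1
        b1 = self.beta1
        for p, m, u in zip(self.params, self._m, self._u):
            m *= b1
            m += (1 - b1) * p.grad
            np.maximum(self.beta2 * u, np.abs(p.grad), out=u)
            p.value -= self.lr * m / ((1 - b1 ** self._t) * (u + self.eps))


_REGISTRY = {
    "sgd": SGD,
    "rmsprop": RMSProp,
    "adadelta": Adadelta,
    "adam": Adam,
    "adamax": Adamax,
}


def make_optimizer(name: str, params, lr: float, **kwargs) -> Optimizer:
    key = name.lower()
    if key not in _REGISTRY:
        raise ValueError(f"unknown optimizer {name!r}; choose from "
                         f"{sorted(_REGISTRY)}")
    return _REGISTRY[key](params, lr, **kwargs)
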