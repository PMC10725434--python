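"""First-order optimizers with inverse-time learning-rate decay.

The effective step size at update ``t`` (0-based) is
``lr / (1 + decay * t)``; ``decay=0`` keeps it constant. NAG is SGD
with Nesterov momentum 0.9.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, lr: float, decay: float = 0.0):
        if lr <= 0:
            raise ValueError(f"learning rate must be > 0, got {lr}")
        if decay < 0:
            raise ValueError(f"decay must be >= 0, got {decay}")
        self.lr = lr
        self.decay = decay
        self.t = 0
        self.state: dict[int, dict] = {}

    def _lr(self) -> float:
        return self.lr / (1.0 + self.decay * self.t)

    def step(self, params: list) -> None:
        """Apply one update to [(layer, name)] pairs using layer.grads."""
        lr = self._lr()
        for i, (layer, name) in enumerate(params):
            g = layer.grads.get(name)
            if g is None:
                continue
            slot = self.state.setdefault(i, {})
            layer.params[name] = self._update(layer.params[name], g.astype(layer.params[name].dtype), lr, slot)
        self.t += 1

    def _update(self, p, g, lr, slot):
        raise NotImplementedError


class SGD(Optimizer):
    def _update(self, p, g, lr, slot):
        return p - lr * g


class NAG(Optimizer):
    momentum = 0.9

    def _update(self, p, g, lr, slot):
        v = slot.get("v", np.zeros_like(p))
        v = self.momentum * v - lr * g
        slot["v"] = v
        return p + self.momentum * v - lr * g


class Adagrad(Optimizer):
    eps = 1e-8

    def _update(self, p, g, lr, slot):
        acc = slot.get("acc", np.zeros_like(p))
        acc = acc + g * g
        slot["acc"] = acc
        return p - lr * g / (np.sqrt(acc) + self.eps)


class RMSprop(Optimizer):
    rho = 0.9
    eps = 1e-8

    def _update(self, p, g, lr, slot):
        acc = slot.get("acc", np.zeros_like(p))
        acc = self.rho * acc + (1 - self.rho) * g * g
        slot["acc"] = acc
        return p - lr * g / (np.sqrt(acc) + self.eps)


class Adam(Optimizer):
    beta1 = 0.9
    beta2 = 0.999
    eps = 1e-8

    def _update(self, p, g, lr, slot):
        m = slot.get("m", np.zeros_like(p))
        v = slot.get("v", np.zeros_like(p))
        k = slot.get("k", 0) + 1
        m = self.beta1 * m + (1 - self.beta1) * g
        v = self.beta2 * v + (1 - self.beta2) * g * g
        slot.update(m=m, v=v, k=k)
        mhat = m / (1 - self.beta1**k)
        vhat = v / (1 - self.beta2**k)
        return p - lr * mhat / (np.sqrt(vhat) + self.eps)


OPTIMIZERS = {
    "sgd": SGD,
    "nag": NAG,
    "adagrad": Adagrad,
    "rmsprop": RMSprop,
    "adam": Adam,
}


def make_optimizer(name: str, lr: float, decay: float = 0.0) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}"
        ) from None
    return cls(lr, decay)
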