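"""Gradient-based optimizers operating on autodiff parameter tensors."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD", "Adam", "RMSProp"]


class _Optimizer:
    def __init__(self, params, lr):
        self.params = list(params)
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = float(lr)

    def step(self, grads):
        raise NotImplementedError

    def scale_lr(self, factor):
        self.lr *= float(factor)


class SGD(_Optimizer):
    """Plain gradient descent."""

    def step(self, grads):
        for p, g in zip(self.params, grads):
            p.data -= self.lr * g.data


class Adam(_Optimizer):
    """Adam with decoupled weight decay.

    Defaults follow the adversarial-training configuration used throughout
    the package: beta1=0.5, beta2=0.99, weight decay 2e-5.
    """

    def __init__(self, params, lr=1e-4, beta1=0.5, beta2=0.99,
                 weight_decay=2e-5, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2 = float(beta1), float(beta2)
        self.weight_decay, self.eps = float(weight_decay), float(eps)
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


class RMSProp(_Optimizer):
    """RMSProp (used by the 4-neuron toy experiment)."""

    def __init__(self, params, lr=1e-3, alpha=0.99, eps=1e-8):
        super().__init__(params, lr)
        self.alpha, self.eps = float(alpha), float(eps)
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads):
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data
            self.v[i] = self.alpha * self.v[i] + (1 - self.alpha) * gd * gd
            p.data -= self.lr * gd / (np.sqrt(self.v[i]) + self.eps)
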