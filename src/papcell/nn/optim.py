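"""Optimizers (Adam only; every model in the package trains with Adam)."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, module, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.module = module
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple] = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for layer in self.module.layers():
            if getattr(layer, "frozen", False):
                continue
            for name in layer.param_shapes():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (id(layer), name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(layer.params[name]),
                                       np.zeros_like(layer.params[name]))
                m, v = self.state[key]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                layer.params[name] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for layer in self.module.layers():
            layer.zero_grad()
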