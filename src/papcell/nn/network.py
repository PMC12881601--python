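"""Containers, parameter accounting and weight (de)serialization."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


class Module:
    """Anything with a flat list of layers; subclasses wire the topology."""

    def layers(self) -> list[Layer]:  # pragma: no cover - abstract
        raise NotImplementedError

    # -- building -----------------------------------------------------------
    def build(self, rng: np.random.Generator):
        for layer in self.layers():
            if not layer.built:
                layer.build(rng)
        return self

    @property
    def built(self) -> bool:
        return all(l.built for l in self.layers())

    # -- parameter access ---------------------------------------------------
    def trainable_layers(self):
        return [l for l in self.layers() if l.param_shapes()]

    def parameters(self):
        """(layer, name, array) triples for every trainable parameter."""
        out = []
        for layer in self.layers():
            for name in layer.param_shapes():
                out.append((layer, name, layer.params[name]))
        return out

    def set_dropout_rng(self, rng: np.random.Generator):
        for layer in self.layers():
            if hasattr(layer, "rng"):
                layer.rng = np.random.default_rng(rng.integers(2 ** 31))

    def get_weights(self):
        return [copy.deepcopy((l.params, l.non_trainable)) for l in self.layers()]

    def set_weights(self, weights):
        for layer, (params, nt) in zip(self.layers(), weights):
            layer.params = copy.deepcopy(params)
            layer.non_trainable = copy.deepcopy(nt)
            layer.built = True

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, training=False):
        return self.forward(x, training=training)


class Sequential(Module):
    def __init__(self, layers):
        self._layers = list(layers)

    def layers(self):
        return self._layers

    def forward(self, x, training=False):
        for layer in self._layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self._layers):
            dout = layer.backward(dout)
        return dout


def count_module_parameters(module: Module):
    """(total, trainable, non_trainable) from shapes alone (no allocation)."""
    trainable = 0
    non_trainable = 0
    for layer in module.layers():
        for shape in layer.param_shapes().values():
            trainable += int(np.prod(shape))
        for shape in layer.non_trainable_shapes().values():
            non_trainable += int(np.prod(shape))
        if getattr(layer, "frozen", False):
            non_trainable += sum(int(np.prod(s)) for s in layer.param_shapes().values())
            trainable -= sum(int(np.prod(s)) for s in layer.param_shapes().values())
    return trainable + non_trainable, trainable, non_trainable
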