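"""Minimal layer/module machinery for the networks in this package.

Layers hold :class:`Parameter` objects (value + accumulated gradient), cache
whatever the backward pass needs during ``forward``, and implement
``backward(grad_out) -> grad_in`` with gradients accumulated into
``Parameter.grad``.  All state is plain numpy, so checkpoints are ``npz``
archives and runs are bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient buffer."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: parameter traversal, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def submodules(self):
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
                yield from value.submodules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item.submodules()

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for m in self.submodules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0

    # -- persistence ---------------------------------------------------
    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, value in self._named_buffers():
            state[name] = value.copy()
        return state

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data[...] = value
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            if name.startswith("buf_") and isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value._named_buffers(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{prefix}{name}.{i}.")

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
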