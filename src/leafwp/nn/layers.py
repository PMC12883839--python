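"""Layers and modules built on the autodiff tensor.

Initialization follows the usual conventions for these layer families:
He-normal fan-in scaling for convolutional weights, Glorot-uniform for
fully connected ones; every constructor takes an explicit numpy Generator
so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv1d, depthwise_conv1d

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "DepthwiseConv1d",
    "BatchNorm1d",
    "Sequential",
    "ReLU",
]


class Module:
    """Base class tracking parameters and submodules by attribute assignment."""

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self) -> "Module":
        object.__setattr__(self, "training", True)
        for m in self._modules.values():
            m.train()
        return self

    def eval(self) -> "Module":
        object.__setattr__(self, "training", False)
        for m in self._modules.values():
            m.eval()
        return self

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (views), for checkpoint/compare."""
        return [p.data for p in self.parameters()]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Fully connected layer, Glorot-uniform initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.weight = Tensor(rng.uniform(-limit, limit, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution ('same' padding), He-normal initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        std = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class DepthwiseConv1d(Module):
    """Per-channel 1-D convolution ('same' padding), He-normal initialized."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for 'same' padding")
        std = np.sqrt(2.0 / kernel)
        self.weight = Tensor(rng.normal(0.0, std, (channels, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Batch normalization per channel/feature.

    Accepts (B, C, L) input (statistics over batch and length per channel)
    or (B, C) input (statistics over the batch per feature). Uses batch
    statistics while training and exponential running statistics in
    inference mode, so evaluation is deterministic and batch-size free.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2) if x.ndim == 3 else (0,)
        stat_shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(stat_shape))
            var = Tensor(self.running_var.reshape(stat_shape))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        g = self.gamma.reshape(*stat_shape)
        b = self.beta.reshape(*stat_shape)
        return xhat * g + b


def reestimate_batchnorm(module: Module, forward, *args) -> None:
    """Reset running statistics of every BatchNorm in ``module`` to the
    statistics of one full forward pass (momentum temporarily 1).

    Call after training so inference-mode normalization reflects the final
    parameters rather than an exponential average over the whole run.
    """
    bns = [m for m in _iter_modules(module) if isinstance(m, BatchNorm1d)]
    saved = [bn.momentum for bn in bns]
    was_training = module.training
    for bn in bns:
        bn.momentum = 1.0
    module.train()
    forward(*args)
    for bn, m in zip(bns, saved):
        bn.momentum = m
    if not was_training:
        module.eval()


def _iter_modules(module: Module):
    yield module
    for m in module._modules.values():
        yield from _iter_modules(m)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer_{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
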