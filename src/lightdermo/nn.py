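"""Neural-network layer primitives built on the autograd tensor.

Layers follow the conventional container pattern: a :class:`Module` owns
:class:`Parameter` leaves (trainable) and buffers (running statistics), and
``parameters()`` / ``state_dict()`` walk the tree.  Convolutions are biasless
by design — every convolution in the architecture is followed by batch
normalization, which subsumes the bias.
"""

from __future__ import annotations

import numpy as np

from ._tensor import (
    ACTIVATIONS,
    Tensor,
    conv2d,
    linear,
    maxpool2x2,
)

__all__ = [
    "Activation",
    "BatchNorm2d",
    "Conv2d",
    "GlobalAvgPool",
    "Linear",
    "MaxPool2x2",
    "Module",
    "Parameter",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: tracks sub-modules, parameters and buffers by attribute."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- tree walking ---------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in self._buffers.items():
            yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def parameter_count(self) -> int:
        """Number of trainable scalars in this module (buffers excluded)."""
        return int(sum(p.data.size for p in self.parameters()))

    # -- modes / state --------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        buffers = dict(self.named_buffers())
        for name in buffers:
            key = "buffer:" + name
            if key in state:
                buffers[name][...] = state[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Biasless grouped 2-D convolution with He-normal init."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 groups=1, rng=None):
        super().__init__()
        if in_channels % groups:
            raise ValueError(f"in_channels {in_channels} not divisible by groups {groups}")
        kh = kw = int(kernel_size)
        fan_in = (in_channels // groups) * kh * kw
        rng = rng or np.random.default_rng()
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels // groups, kh, kw))
        )
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x):
        return conv2d(x, self.weight, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    """Batch normalization with learnable scale and shift (2 params/channel)."""

    def __init__(self, channels, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps, self.momentum = eps, momentum
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            bessel = n / max(n - 1, 1)
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(C)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * bessel * var.data.reshape(C)
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = self._buffers["running_mean"].reshape(1, C, 1, 1)
            sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(1, C, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        g = self.gamma.reshape(1, C, 1, 1)
        b = self.beta.reshape(1, C, 1, 1)
        return xhat * g + b


class Linear(Module):
    def __init__(self, in_features, out_features, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / in_features), (in_features, out_features))
        )
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        return linear(x, self.weight, self.bias)


class Activation(Module):
    def __init__(self, name: str = "gelu"):
        super().__init__()
        key = name.lower().replace("_", "").replace("-", "")
        if key not in ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")
        self.name = key
        self._fn = ACTIVATIONS[key]

    def forward(self, x):
        return self._fn(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return maxpool2x2(x)


class GlobalAvgPool(Module):
    def forward(self, x):
        return x.mean(axis=(2, 3))
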