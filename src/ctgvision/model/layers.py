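"""Neural-network layers on top of the autograd core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        def walk(obj):
            if isinstance(obj, Module):
                yield obj
                for v in obj.__dict__.values():
                    yield from walk(v)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    yield from walk(item)
        yield from walk(self)

    def named_parameters(self):
        for i, m in enumerate(self.modules()):
            for name, v in m.__dict__.items():
                if isinstance(v, Parameter):
                    yield f"{i}.{type(m).__name__}.{name}", v

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"{i}.running_mean"] = m.running_mean.copy()
                state[f"{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = state[f"{i}.running_mean"].copy()
                m.running_var = state[f"{i}.running_var"].copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Dense convolution; ``padding=None`` means same-padding (odd kernels)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_channels * kernel * kernel
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution (one filter per channel)."""

    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = kernel // 2
        self.weight = Parameter(
            _kaiming(rng, (channels, kernel, kernel), kernel * kernel))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias, self.stride,
                                   self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            _kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training, self.momentum,
                             self.eps)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(x)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(x)


class Dropout(Module):
    def __init__(self, p: float, seed: int = 0):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.p, self.rng, self.training)
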