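"""Parameterised layers built on the autodiff primitives."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Parameter", "Module", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "Linear"]

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal module base: parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        """Number of trainable scalars."""
        return int(sum(p.data.size for p in self.parameters()))

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bnstate{i}.mean"] = m.running_mean.copy()
                state[f"__bnstate{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bnstate{i}.mean"], dtype=DTYPE).copy()
                m.running_var = np.asarray(state[f"__bnstate{i}.var"], dtype=DTYPE).copy()


def _trunc_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) truncated at two standard deviations."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(DTYPE)


class Conv2d(Module):
    """Bias-free dense convolution (batch norm supplies the affine terms)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.padding = kernel // 2
        rng = rng or np.random.default_rng(0)
        fan_out = kernel * kernel * out_ch
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Parameter(_trunc_normal(rng, (out_ch, in_ch, kernel, kernel), std))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        return T.conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    """Per-channel spatial convolution, bias-free."""

    def __init__(self, channels: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels, self.kernel, self.stride = channels, kernel, stride
        self.padding = kernel // 2
        rng = rng or np.random.default_rng(0)
        fan_out = kernel * kernel
        std = float(np.sqrt(2.0 / fan_out))
        self.weight = Parameter(_trunc_normal(rng, (channels, kernel, kernel), std))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return T.dwconv2d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        return T.batchnorm2d(x, self.gamma, self.beta,
                             self.running_mean, self.running_var,
                             training=self.training, momentum=self.momentum,
                             eps=self.eps)


class Linear(Module):
    """Fully connected layer with bias; uniform fan-in initialisation."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        rng = rng or np.random.default_rng(0)
        bound = float(1.0 / np.sqrt(in_features))
        self.weight = Parameter(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(DTYPE))
        self.bias = Parameter(
            rng.uniform(-bound, bound, size=(out_features,)).astype(DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_features:
            raise ValueError(f"expected width {self.in_features}, got {x.shape[1]}")
        return T.add(T.matmul(x, self.weight), self.bias)
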