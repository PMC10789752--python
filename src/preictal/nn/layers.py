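"""Neural-network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d

DTYPE = np.float32


class Module:
    """Base class: parameter discovery via attributes, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        def walk(value):
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    yield from walk(item)

        for v in self.__dict__.values():
            yield from walk(v)

    def parameters(self):
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    yield v

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        """Flat name -> array mapping of parameters and buffers."""
        out = {}

        def visit(value, name):
            if isinstance(value, Tensor) and value.requires_grad:
                out[name] = value.data
            elif isinstance(value, np.ndarray):
                out[name] = value
            elif isinstance(value, Module):
                for k, v in value.__dict__.items():
                    visit(v, f"{name}.{k}")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    visit(item, f"{name}.{i}")

        for k, v in self.__dict__.items():
            visit(v, k)
        return out

    def load_state_dict(self, state: dict):
        def visit(owner, key, value, name):
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = np.asarray(state[name], dtype=value.data.dtype)
            elif isinstance(value, np.ndarray):
                if isinstance(owner, Module):
                    owner.__dict__[key] = np.asarray(state[name],
                                                     dtype=value.dtype)
            elif isinstance(value, Module):
                for k, v in value.__dict__.items():
                    visit(value, k, v, f"{name}.{k}")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    visit(value, i, item, f"{name}.{i}")

        for k, v in self.__dict__.items():
            visit(self, k, v, k)
        return self


class Conv2d(Module):
    """3x3 (or kxk) convolution, no bias (always followed by batch norm)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, std, (out_channels, in_channels,
                                  kernel_size, kernel_size)).astype(DTYPE),
            requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel.

    The normalisation is composed from differentiable primitives, so the
    backward pass needs no dedicated formula.  Running statistics
    (exponential moving average) are used in eval mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, num_features, 1, 1), dtype=DTYPE),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, num_features, 1, 1), dtype=DTYPE),
                           requires_grad=True)
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=DTYPE)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.astype(DTYPE))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.astype(DTYPE))
            inv = (var + self.eps).sqrt()
            return xc / inv * self.gamma + self.beta
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return x * Tensor(scale) + Tensor(shift)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, std, (in_features, out_features)).astype(DTYPE),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.9):
        if lr < 0:
            raise ValueError("learning rate must be nonnegative")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        if self.lr == 0.0:
            return
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data = p.data - self.lr * v
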