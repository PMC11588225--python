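"""Layers and optimisation on top of the autograd engine.

The conventions mirror the common deep-learning stacks: feature maps are
(batch, channel, row, col); a "conv unit" is convolution + batch
normalisation + ReLU; gating convolutions (those whose output feeds a
sigmoid) keep the normalisation but drop the ReLU so the gate sees signed
values.  Convolution weights use Kaiming-uniform initialisation
(bound = sqrt(6 / fan_in)), batch-norm affine terms start at gamma=1,
beta=0, and every draw comes from an explicitly passed numpy Generator so
whole-network construction is seeded.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A tensor updated by the optimiser."""

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


class Module:
    """Minimal module tree: parameter discovery, train/eval mode, zero_grad."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, value in self.__dict__.items():
            path = f"{prefix}.{key}" if prefix else key
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- (de)serialisation ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for key, value in self.__dict__.items():
            path = f"{prefix}.{key}" if prefix else key
            if isinstance(value, Module):
                yield from value.named_buffers(path)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}")
            elif key.startswith("running_") and isinstance(value, np.ndarray):
                yield path, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name}")
                params[name].data = np.asarray(value, dtype=params[name].data.dtype)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown entry in state dict: {name}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]}")


def kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    """Stride-1 2-D convolution with zero padding preserving spatial size."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, dilation: int = 1, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            kaiming_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, num_features: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centred = x - mean
            var = (centred * centred).mean(axis=(0, 2, 3), keepdims=True)
            n = x.size / self.num_features
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            inv = (var + self.eps) ** -0.5
            xhat = centred * inv
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - mean) * inv.reshape(1, -1, 1, 1)
        g = self.gamma.reshape((1, self.num_features, 1, 1))
        b = self.beta.reshape((1, self.num_features, 1, 1))
        return xhat * g + b


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ConvUnit(Module):
    """conv -> [batch norm] -> [ReLU]; the building block of every branch."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, *, dilation: int = 1,
                 norm: bool = True, act: bool = True):
        super().__init__()
        # a conv bias preceding batch norm is cancelled by the mean
        # subtraction, so it is only created when normalisation is off
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng,
                           dilation=dilation, bias=not norm)
        self.norm = BatchNorm2d(out_channels) if norm else Identity()
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return ag.relu(y) if self.act else y


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
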