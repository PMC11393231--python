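"""Neural-network building blocks on top of the autodiff engine.

Parameter containers, fan-in-scaled initialisation, 3D convolution /
transposed-convolution / normalisation layers, a linear layer and the
Adam optimiser with an optional cosine learning-rate schedule.  All
randomness is injected through ``numpy.random.Generator`` objects so a
single root seed determines every weight.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv3d, conv_transpose3d

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "LayerNorm",
    "Linear",
    "Adam",
    "activation",
]

DTYPE = np.float32


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and state dicts."""

    def __init__(self) -> None:
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, value in vars(self).items():
            if isinstance(value, Module):
                value.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules = list(modules)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def append(self, module: Module) -> None:
        self._modules.append(module)

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_parameters(prefix=f"{prefix}{i}.")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = math.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


def activation(x: Tensor, kind: str) -> Tensor:
    if kind == "leaky_relu":
        return x.leaky_relu(0.01)
    if kind == "relu":
        return x.relu()
    raise ValueError(f"unknown activation kind {kind!r}")


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if padding is None:
            padding = kernel // 2
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel ** 3
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """2x2x2 transposed convolution with stride 2 (the decoder upsampler)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * 8
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, 2, 2, 2), fan_in))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gain = Parameter(np.ones((1, channels, 1, 1, 1)))
            self.bias = Parameter(np.zeros((1, channels, 1, 1, 1)))
        else:
            self.gain = None
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        axes = (2, 3, 4)
        mu = x.mean(axis=axes, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=axes, keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        if self.gain is not None:
            y = y * self.gain + self.bias
        return y


class LayerNorm(Module):
    """Normalisation over the trailing (feature/channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.eps = eps
        if affine:
            self.gain = Parameter(np.ones(dim))
            self.bias = Parameter(np.zeros(dim))
        else:
            self.gain = None
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        y = xc * (var + self.eps) ** -0.5
        if self.gain is not None:
            y = y * self.gain + self.bias
        return y


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        if self.bias is not None:
            yield f"{prefix}bias", self.bias

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Adam:
    """Adam with optional cosine decay and global-norm gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, total_steps: int | None = None,
                 cosine: bool = False, max_grad_norm: float | None = None):
        self.params = list(params)
        self.base_lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.cosine = cosine
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def current_lr(self) -> float:
        if self.cosine and self.total_steps:
            frac = min(self.t / self.total_steps, 1.0)
            return self.base_lr * 0.5 * (1.0 + math.cos(math.pi * frac))
        return self.base_lr

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.max_grad_norm is not None:
            total = math.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads))
            if total > self.max_grad_norm and total > 0:
                scale = self.max_grad_norm / total
                grads = [g * scale for g in grads]
        lr = self.current_lr()
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data.astype(np.float64) - update).astype(p.data.dtype)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64) for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64) for v in state["v"]]
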