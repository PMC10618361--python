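"""Layer zoo on top of the autodiff engine.

Layers hold :class:`Parameter` leaves and compose via :class:`Module`, whose
parameter discovery walks attributes recursively (lists included) in
deterministic order so checkpoints round-trip exactly.
"""

from __future__ import annotations

from typing import Iterator, List, Optional, Tuple

import numpy as np

from . import autograd as A
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor leaf."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter traversal, gradient reset, state dict."""

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, value in sorted(vars(self).items()):
            yield from _walk_params(value, f"{prefix}{name}")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, value in sorted(vars(self).items()):
            yield from _walk_modules(value)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()


def _walk_params(value, prefix: str) -> Iterator[Tuple[str, Parameter]]:
    if isinstance(value, Parameter):
        yield prefix, value
    elif isinstance(value, Module):
        yield from value.named_parameters(f"{prefix}.")
    elif isinstance(value, (list, tuple)):
        for i, item in enumerate(value):
            yield from _walk_params(item, f"{prefix}.{i}")


def _walk_modules(value) -> Iterator[Module]:
    if isinstance(value, Module):
        yield from value.modules()
    elif isinstance(value, (list, tuple)):
        for item in value:
            yield from _walk_modules(item)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        k = int(kernel_size)
        fan_in = in_channels * k ** 3
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = int(stride)
        self.padding = int(padding)
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.last_output_voxels: Optional[int] = None

    def forward(self, x):
        out = A.conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)
        self.last_output_voxels = int(np.prod(out.shape[2:]))
        return out


class ConvTranspose3d(Module):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = 2
        self.weight = Parameter(_he_init(rng, (in_channels, out_channels, 2, 2, 2), in_channels * 8))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.last_output_voxels: Optional[int] = None

    def forward(self, x):
        out = A.conv_transpose3d_2x(x, self.weight, self.bias)
        self.last_output_voxels = int(np.prod(out.shape[2:]))
        return out


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        return A.instance_norm(x, self.weight, self.bias, self.eps)


class PReLU(Module):
    def __init__(self, channels: int, init: float = 0.25):
        self.weight = Parameter(np.full(channels, init, dtype=np.float32))

    def forward(self, x):
        return A.prelu(x, self.weight)


class ReLU(Module):
    def forward(self, x):
        return A.relu(x)


class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_he_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x):
        return A.matmul(x, self.weight) + self.bias


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer over a parameter list; lr may be reassigned per epoch."""

    def __init__(self, params: List[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
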