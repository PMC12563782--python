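"""Module system: Conv2d, BatchNorm2d, Linear, activations, containers."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "SiLU",
    "Sigmoid",
    "MaxPool2d",
    "Sequential",
    "Identity",
]


class Parameter(Tensor):
    def __init__(self, data: np.ndarray):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Tiny nn.Module analogue: parameter discovery, train/eval, state dict."""

    def __init__(self):
        self._training = True

    def __call__(self, *a, **k):
        return self.forward(*a, **k)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
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

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m._training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # buffers (running BN stats) are discovered by attribute convention
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._named_buffers():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self._named_buffers())
        for k, v in state.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=np.float32).reshape(params[k].data.shape)
            elif k in bufs:
                bufs[k][...] = np.asarray(v).reshape(bufs[k].shape)
            else:
                raise KeyError(f"unexpected state entry {k!r}")

    def _named_buffers(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, np.ndarray) and name.startswith("running_"):
                yield key, v
            elif isinstance(v, Module):
                yield from v._named_buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._named_buffers(f"{key}.{i}.")


_init_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Reseed the parameter-initialisation stream (call before building a model)."""
    global _init_rng
    _init_rng = np.random.default_rng(seed)


def _kaiming(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (_init_rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming((cout, cin, kernel, kernel), cin * kernel * kernel))
        self.bias = Parameter(np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.weight = Parameter(_kaiming((cin, cout, 2, 2), cin * 4))
        self.bias = Parameter(np.zeros(cout, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c, np.float32))
        self.bias = Parameter(np.zeros(c, np.float32))
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self._training:
            out, mu, var = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var
                                + m * unbias * var).astype(np.float32)
            return out
        scale = self.weight.data / np.sqrt(self.running_var + self.eps)
        shift = self.bias.data - self.running_mean * scale
        return x * Tensor(scale.reshape(1, -1, 1, 1)) + Tensor(shift.reshape(1, -1, 1, 1))


class Linear(Module):
    def __init__(self, cin: int, cout: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming((cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x
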