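"""Neural-network building blocks on the autodiff Tensor.

Layers follow the usual (N, C, H, W) / (N, C, L) conventions.  Convolutions
are implemented with ``sliding_window_view`` + ``einsum`` for the forward pass
and an explicit kernel-offset scatter for the input gradient; both paths are
finite-difference checked in the test suite.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = [
    "Parameter", "Module", "Sequential", "Linear", "Conv2d", "Conv1d",
    "ReLU", "GlobalAvgPool2d", "softmax", "log_softmax", "logsumexp",
    "cross_entropy", "l2_normalize",
]


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data)
        self.requires_grad = True  # parameters always track gradients


class Module:
    """Minimal module base: parameter registration, state dict, train/eval."""

    def __init__(self):
        self._parameters: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._parameters.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._parameters.items():
            yield (f"{prefix}{n}", p)
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{mn}.")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: np.array(p.data, copy=True) for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for n, p in own.items():
            arr = np.asarray(state[n], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {n}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.layers:
            x = m(x)
        return x


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


def _pad_hw(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    return np.pad(x, width)


class Conv2d(Module):
    """2D convolution (cross-correlation), square kernel, symmetric padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        self.stride = int(stride)
        self.padding = int(padding)
        self.kernel_size = int(kernel_size)
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        s, p, k = self.stride, self.padding, self.kernel_size
        xp = _pad_hw(x.data, p)
        n, c, hp, wp = xp.shape
        h_out = (hp - k) // s + 1
        w_out = (wp - k) // s + 1
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        windows = windows[:, :, ::s, ::s, :, :]  # (N, C, Ho, Wo, k, k)
        out = np.einsum("nchwij,ocij->nohw", windows, w.data, optimize=True)
        out += b.data[None, :, None, None]

        def backward(g):
            gw = np.einsum("nohw,nchwij->ocij", g, windows, optimize=True)
            gb = g.sum(axis=(0, 2, 3))
            gxp = np.zeros((n, c, hp, wp))
            for i in range(k):
                for j in range(k):
                    # contribution of kernel offset (i, j) to the padded input
                    contrib = np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j],
                                        optimize=True)
                    gxp[:, :, i:i + s * h_out:s, j:j + s * w_out:s] += contrib
            gx = gxp[:, :, p:hp - p, p:wp - p] if p else gxp
            return (gx, gw, gb)

        return Tensor._make(out, (x, w, b), backward)


class Conv1d(Module):
    """1D convolution over the last axis of (N, C, L)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: str | int = "same"):
        super().__init__()
        self.kernel_size = int(kernel_size)
        if padding == "same":
            if kernel_size % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel size")
            self.padding = (kernel_size - 1) // 2
        else:
            self.padding = int(padding)
        fan_in = in_channels * kernel_size
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k, p = self.kernel_size, self.padding
        xp = np.pad(x.data, [(0, 0), (0, 0), (p, p)]) if p else x.data
        n, c, lp = xp.shape
        l_out = lp - k + 1
        if l_out < 1:
            raise ValueError(
                f"input length {x.data.shape[-1]} shorter than receptive field {k} "
                f"with padding {p}")
        windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (N,C,Lo,k)
        out = np.einsum("nclk,ock->nol", windows, w.data, optimize=True)
        out += b.data[None, :, None]

        def backward(g):
            gw = np.einsum("nol,nclk->ock", g, windows, optimize=True)
            gb = g.sum(axis=(0, 2))
            gxp = np.zeros((n, c, lp))
            for i in range(k):
                gxp[:, :, i:i + l_out] += np.einsum("nol,oc->ncl", g, w.data[:, :, i],
                                                    optimize=True)
            gx = gxp[:, :, p:lp - p] if p else gxp
            return (gx, gw, gb)

        return Tensor._make(out, (x, w, b), backward)


# -- functional helpers -------------------------------------------------------

def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (max is detached)."""
    m = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    out = (shifted.exp().sum(axis=axis, keepdims=True)).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(tuple(s for i, s in enumerate(out.shape) if i != axis % x.ndim))
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x - logsumexp(x, axis=axis, keepdims=True)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def cross_entropy(logits: Tensor, target_index: int) -> Tensor:
    """Negative log-likelihood of ``target_index`` under softmax(logits); 1D logits."""
    return -log_softmax(logits, axis=-1)[target_index]


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm
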