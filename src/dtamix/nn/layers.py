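"""Neural-net building blocks on top of the :mod:`dtamix.nn.tensor` autodiff.

Convolutions are implemented as first-class autodiff nodes (einsum forward,
explicit adjoint backward) because composing them from slice primitives is an
order of magnitude slower in pure Python.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Embedding", "Affine", "BatchNorm",
    "Dropout", "GroupedConv1d", "Conv2d",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Parameter container with train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        for value in vars(self).values():
            if isinstance(value, Parameter):
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown parameter {name!r} in checkpoint")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{key}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{key}.{i}.")
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                yield key, value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, in_features, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator,
                 pad_index: int | None = 0):
        super().__init__()
        table = rng.normal(0.0, 0.1, size=(n_tokens, dim))
        if pad_index is not None:
            table[pad_index] = 0.0
        self.weight = Parameter(table)

    def forward(self, indices: np.ndarray) -> Tensor:
        return self.weight.take_rows(indices)


class Affine(Module):
    """Per-channel scale and shift: ``x * alpha + beta``."""

    def __init__(self, channels: int):
        super().__init__()
        self.alpha = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.alpha + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.shape) < keep
        return x * Tensor(mask / keep)


class BatchNorm(Module):
    """Normalizes the trailing channel axis over all leading axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            axes = tuple(range(x.ndim - 1))
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu.data.reshape(-1)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * var.data.reshape(-1)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


def _autodiff_node(data: np.ndarray, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


_EINSUM_PATHS: dict[tuple, list] = {}


def _einsum(subscripts: str, *operands: np.ndarray) -> np.ndarray:
    """einsum with a memoized contraction path (per subscript + shapes)."""
    key = (subscripts, tuple(op.shape for op in operands))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *operands, optimize="optimal")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(subscripts, *operands, optimize=path)


class GroupedConv1d(Module):
    """'same'-padded grouped 1-D convolution along the length axis.

    Input ``(B, L, C_in)`` → output ``(B, L, C_out)``; channels are split into
    ``groups`` independent blocks. Kernel size must be odd.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 groups: int, rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for symmetric padding")
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}, {out_channels}) not divisible by "
                f"groups={groups}")
        self.kernel_size = kernel_size
        self.groups = groups
        cin_g, cout_g = in_channels // groups, out_channels // groups
        fan_in = kernel_size * cin_g
        self.weight = Parameter(_kaiming(rng, fan_in,
                                         (kernel_size, groups, cin_g, cout_g)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        K, G = self.kernel_size, self.groups
        B, L, C = x.shape
        w, b = self.weight, self.bias
        half = K // 2
        xp = np.pad(x.data, ((0, 0), (half, half), (0, 0)))
        xg = xp.reshape(B, L + K - 1, G, C // G)
        win = np.lib.stride_tricks.sliding_window_view(xg, K, axis=1)
        # win: (B, L, G, C/G, K) strided view, no copy
        y = _einsum("blgik,kgio->blgo", win, w.data)
        y = y.reshape(B, L, C) + b.data

        def backward(g):
            gy = g.reshape(B, L, G, -1)
            if w.requires_grad:
                w._accum(_einsum("blgik,blgo->kgio", win, gy))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1)))
            if x.requires_grad:
                # full correlation of the upstream gradient with the
                # spatially flipped kernel recovers the input gradient
                gp = np.pad(gy, ((0, 0), (K - 1, K - 1), (0, 0), (0, 0)))
                gwin = np.lib.stride_tricks.sliding_window_view(gp, K, axis=1)
                wf = w.data[::-1]  # (K, G, Cin_g, Cout_g) flipped along K
                gxp = _einsum("bpgok,kgio->bpgi", gwin, wf)
                x._accum(gxp.reshape(B, L + K - 1, C)[:, half:half + L, :])

        return _autodiff_node(y, (x, w, b), backward)


class Conv2d(Module):
    """'same'-padded dense 2-D convolution over ``(B, H, W, C_in)`` maps."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd for symmetric padding")
        self.kernel_size = kernel_size
        fan_in = kernel_size * kernel_size * in_channels
        self.weight = Parameter(
            _kaiming(rng, fan_in,
                     (kernel_size, kernel_size, in_channels, out_channels)))
        self.bias = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        K = self.kernel_size
        half = K // 2
        B, H, W, C = x.shape
        w, b = self.weight, self.bias
        xp = np.pad(x.data, ((0, 0), (half, half), (half, half), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (K, K), axis=(1, 2))
        # win: (B, H, W, C, K, K) strided view
        y = _einsum("bhwcij,ijco->bhwo", win, w.data) + b.data

        def backward(g):
            if w.requires_grad:
                w._accum(_einsum("bhwcij,bhwo->ijco", win, g))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 1, 2)))
            if x.requires_grad:
                gp = np.pad(g, ((0, 0), (K - 1, K - 1), (K - 1, K - 1), (0, 0)))
                gwin = np.lib.stride_tricks.sliding_window_view(
                    gp, (K, K), axis=(1, 2))
                wf = w.data[::-1, ::-1]
                gxp = _einsum("bpqoij,ijco->bpqc", gwin, wf)
                x._accum(gxp[:, half:half + H, half:half + W, :])

        return _autodiff_node(y, (x, w, b), backward)
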