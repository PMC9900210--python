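"""Token-mixing sequence encoders for drugs and proteins.

Each encoder block is a *global* extractor — a residual fully-connected stack
acting along the length axis (token mixing) wrapped in per-channel affine
transforms — followed by an *individual* extractor that works per element:
a channel-axis MLP for drugs, a stack of large-kernel grouped 1-D
convolutions for proteins, both gated by a 2-D-convolutional spatial
attention map.

All forwards take ``(B, L, C)`` batches.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .nn import (Affine, BatchNorm, Conv2d, GroupedConv1d, Linear, Module,
                 Tensor)

__all__ = [
    "GlobalFeatureExtractor", "SpatialAttention", "BioMLPIndividual",
    "BioCNNIndividual", "BioMLPBlock", "BioCNNBlock", "DrugEncoder",
    "ProteinEncoder", "affine",
]


def affine(x: Tensor, alpha, beta) -> Tensor:
    """Per-channel scale and shift: broadcast ``x * alpha + beta``."""
    alpha = np.asarray(alpha, dtype=np.float64)
    beta = np.asarray(beta, dtype=np.float64)
    if alpha.shape[-1] != x.shape[-1] or beta.shape[-1] != x.shape[-1]:
        raise ValueError(
            f"affine params of width {alpha.shape[-1]}/{beta.shape[-1]} do not "
            f"match channel dim {x.shape[-1]}")
    return x * Tensor(alpha) + Tensor(beta)


class GlobalFeatureExtractor(Module):
    """Residual length-axis mixer: ``X + AF(FC3(AF(X)^T)^T)``.

    FC3 is three fully-connected layers (width L, two rectifiers) applied to
    the transposed map, i.e. it mixes positions, not channels.
    """

    def __init__(self, length: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.length = length
        self.af_in = Affine(channels)
        self.fc1 = Linear(length, length, rng)
        self.fc2 = Linear(length, length, rng)
        self.fc3 = Linear(length, length, rng)
        self.af_out = Affine(channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-2] != self.length:
            raise ValueError(
                f"expected length {self.length}, got {x.shape[-2]}")
        h = self.af_in(x).T            # (B, C, L)
        h = self.fc1(h).relu()
        h = self.fc2(h).relu()
        h = self.fc3(h)
        return x + self.af_out(h.T)


class SpatialAttention(Module):
    """Gate by a sigmoid 2-D convolution of the map viewed as a 1-channel
    image: ``X * sigmoid(conv2d(X))``."""

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(1, 1, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, l, c = x.shape
        gate = self.conv(x.reshape(b, l, c, 1)).reshape(b, l, c)
        return x * gate.sigmoid()


class BioMLPIndividual(Module):
    """Per-element extractor for drugs:
    ``FC(X + Att(AF(FC2(AF(X)))))`` with FC2 a channel-axis 2-layer MLP."""

    def __init__(self, channels: int, kernel_2d: int, rng: np.random.Generator):
        super().__init__()
        self.af_in = Affine(channels)
        self.fc_a = Linear(channels, channels, rng)
        self.fc_b = Linear(channels, channels, rng)
        self.af_out = Affine(channels)
        self.att = SpatialAttention(kernel_2d, rng)
        self.fc_final = Linear(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.fc_b(self.fc_a(self.af_in(x)).relu())
        return self.fc_final(x + self.att(self.af_out(h)))


class BioCNNIndividual(Module):
    """Per-element extractor for proteins: three large-kernel grouped-conv
    blocks (conv → batch-norm → rectifier) replace the channel MLP."""

    def __init__(self, channels: int, kernel_sizes: tuple[int, int, int],
                 groups: int, kernel_2d: int, rng: np.random.Generator):
        super().__init__()
        self.af_in = Affine(channels)
        self.convs = [GroupedConv1d(channels, channels, k, groups, rng)
                      for k in kernel_sizes]
        self.norms = [BatchNorm(channels) for _ in kernel_sizes]
        self.af_out = Affine(channels)
        self.att = SpatialAttention(kernel_2d, rng)
        self.fc_final = Linear(channels, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.af_in(x)
        for conv, norm in zip(self.convs, self.norms):
            h = norm(conv(h)).relu()
        return self.fc_final(x + self.att(self.af_out(h)))


class BioMLPBlock(Module):
    def __init__(self, length: int, channels: int, kernel_2d: int,
                 rng: np.random.Generator):
        super().__init__()
        self.global_ext = GlobalFeatureExtractor(length, channels, rng)
        self.individual = BioMLPIndividual(channels, kernel_2d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.individual(self.global_ext(x))


class BioCNNBlock(Module):
    def __init__(self, length: int, channels: int,
                 kernel_sizes: tuple[int, int, int], groups: int,
                 kernel_2d: int, rng: np.random.Generator):
        super().__init__()
        self.global_ext = GlobalFeatureExtractor(length, channels, rng)
        self.individual = BioCNNIndividual(channels, kernel_sizes, groups,
                                           kernel_2d, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.individual(self.global_ext(x))


class DrugEncoder(Module):
    """``dn`` stacked BioMLP blocks over an ``(B, L_D, C_D)`` map."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.blocks = [BioMLPBlock(cfg.l_d, cfg.c_d, cfg.kernel_2d, rng)
                       for _ in range(cfg.dn)]

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class ProteinEncoder(Module):
    """``pn`` stacked BioCNN blocks over an ``(B, L_P, C_P)`` map."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        groups = cfg.conv_groups
        if cfg.c_p % groups:
            raise ValueError(f"c_p={cfg.c_p} not divisible by groups={groups}")
        self.blocks = [BioCNNBlock(cfg.l_p, cfg.c_p, cfg.kernel_lk, groups,
                                   cfg.kernel_2d, rng)
                       for _ in range(cfg.pn)]

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x
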