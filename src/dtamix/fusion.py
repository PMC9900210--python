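"""Two-branch feature fusion.

Merges the two representations of one entity (residue-token vs k-mer-token
maps for proteins; fingerprint vs graph maps for drugs) into a single
``L × C_S`` matrix. A convolutional gate computed from both inputs assigns
complementary elementwise weights ``W`` and ``1 − W`` to the two branches:

    fused = FC(X1) * W + X1 + FC(X2) * (1 - W) + X2
    W     = sigmoid(conv2d(stack(X1, X2)))

The two inputs are stacked as two channels of one image for the gate
convolution so that the gate has the branch shape ``L × C_S`` natively.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Linear, Module, Tensor, concat

__all__ = ["ChannelAlign", "ElemFeatureFusion"]


class ChannelAlign(Module):
    """Learned linear projection ``L×C → L×C_S`` (identity when C == C_S)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.identity = in_channels == out_channels
        if not self.identity:
            self.proj = Linear(in_channels, out_channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        return x if self.identity else self.proj(x)


class ElemFeatureFusion(Module):
    def __init__(self, channels: int, kernel_size: int,
                 rng: np.random.Generator, share_fc1: bool = False):
        super().__init__()
        self.fc1_a = Linear(channels, channels, rng)
        self.fc1_b = self.fc1_a if share_fc1 else Linear(channels, channels, rng)
        self.gate_conv = Conv2d(2, 1, kernel_size, rng)

    def attention_weights(self, x1: Tensor, x2: Tensor) -> Tensor:
        b, l, c = x1.shape
        stacked = concat([x1.reshape(b, l, c, 1), x2.reshape(b, l, c, 1)],
                         axis=3)
        return self.gate_conv(stacked).reshape(b, l, c).sigmoid()

    def forward(self, x1: Tensor, x2: Tensor) -> Tensor:
        if x1.shape != x2.shape:
            raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
        w = self.attention_weights(x1, x2)
        return (self.fc1_a(x1).relu() * w + x1
                + self.fc1_b(x2).relu() * (1.0 - w) + x2)
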