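"""Interaction decoder.

Pipeline per pair: sample a ``C_S × C_S`` kernel from the drug feature map,
slide it over the protein map to obtain a per-residue response vector
(whose peak locates the predicted binding region), re-weight the protein map
by the response and the drug map by graph connectivity, enhance each map
with a length-axis softmax gate, mix them with a cross-attention block, and
pool to a fixed-length interaction vector feeding the affinity head.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .nn import Dropout, Linear, Module, Parameter, Tensor, as_tensor, concat

__all__ = [
    "DrugKernelSampler", "compute_response_vector", "predict_binding_region",
    "inject_region_info", "inject_adj_info", "SelfEnhance", "CrossAttend",
    "pool_interaction", "AffinityHead", "MixDecoder",
]


class DrugKernelSampler(Module):
    """Collapse the drug length axis with a learned linear map:
    ``K = Ws^T @ Fd`` with ``Ws`` of shape ``(L_D, C_S)``."""

    def __init__(self, l_d: int, c_s: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0 / np.sqrt(l_d),
                                           size=(l_d, c_s)))

    def forward(self, fd: Tensor) -> Tensor:
        if fd.shape[-2] != self.weight.shape[0]:
            raise ValueError(
                f"drug map length {fd.shape[-2]} does not match sampler "
                f"length {self.weight.shape[0]}")
        return self.weight.T @ fd  # (B, C_S, C_S)


def compute_response_vector(fp: Tensor, kernel: Tensor) -> Tensor:
    """Centered full-channel sliding correlation of the protein map with the
    drug kernel, zero-padded along the length axis.

    ``s[i] = sum_{m,n} K[m, n] * Fp[i + m - C//2, n]`` — one scalar per
    residue, output length L_P.
    """
    fp = as_tensor(fp)
    kernel = as_tensor(kernel)
    squeeze = fp.ndim == 2
    if squeeze:
        fp = fp.reshape(1, *fp.shape)
        kernel = kernel.reshape(1, *kernel.shape)
    b, l, c = fp.shape
    half = c // 2
    fpad = fp.pad(((0, 0), (half, c - 1 - half), (0, 0)))
    s = None
    for m in range(c):
        row = kernel[:, m:m + 1, :]                      # (B, 1, C)
        term = (fpad[:, m:m + l, :] * row).sum(axis=2)   # (B, L)
        s = term if s is None else s + term
    return s.reshape(l) if squeeze else s


def predict_binding_region(s: np.ndarray, scale: int,
                           l_p: int | None = None) -> tuple[int, int]:
    """Interval of length ``scale`` centered on the response peak (smallest
    index on ties), clipped to ``[0, l_p)``."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    s = np.asarray(s)
    if l_p is None:
        l_p = len(s)
    center = int(np.argmax(s))
    start = max(0, center - scale // 2)
    end = min(l_p, center + (scale + 1) // 2)
    return start, end


def inject_region_info(fp: Tensor, s: Tensor) -> Tensor:
    """Scale every channel of residue ``i`` by the response ``s[i]``."""
    fp = as_tensor(fp)
    s = as_tensor(s)
    return fp * s.reshape(*s.shape, 1)


def inject_adj_info(xd: Tensor, adj: np.ndarray) -> Tensor:
    """Scale each atom row by its mean connectivity (row mean of the padded
    adjacency, self-loop included)."""
    xd = as_tensor(xd)
    conn = np.asarray(adj).mean(axis=-1)
    return xd * Tensor(conn[..., np.newaxis])


class SelfEnhance(Module):
    """``(X W1) * softmax_L((X Wm) / C_S)`` — positions compete per channel."""

    def __init__(self, c_s: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(c_s)
        self.w1 = Parameter(rng.normal(0.0, scale, size=(c_s, c_s)))
        self.wm = Parameter(rng.normal(0.0, scale, size=(c_s, c_s)))
        self.c_s = c_s

    def gate(self, x: Tensor) -> Tensor:
        return ((x @ self.wm) / float(self.c_s)).softmax(axis=-2)

    def forward(self, x: Tensor) -> Tensor:
        return (x @ self.w1) * self.gate(x)


class CrossAttend(Module):
    """Residual token-mixing over the concatenated protein+drug map:
    ``Y = Xm + ((Xm Wm1)^T Wm2)^T * softmax_L((Xm Wm) / C_S)``."""

    def __init__(self, n_tokens: int, c_s: int, rng: np.random.Generator):
        super().__init__()
        self.wm1 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(c_s),
                                        size=(c_s, c_s)))
        self.wm2 = Parameter(rng.normal(0.0, 1.0 / np.sqrt(n_tokens),
                                        size=(n_tokens, n_tokens)))
        self.wm = Parameter(rng.normal(0.0, 1.0 / np.sqrt(c_s),
                                       size=(c_s, c_s)))
        self.c_s = c_s

    def gate(self, x: Tensor) -> Tensor:
        return ((x @ self.wm) / float(self.c_s)).softmax(axis=-2)

    def forward(self, xp: Tensor, xd: Tensor) -> Tensor:
        xm = concat([xp, xd], axis=-2)
        mixed = ((xm @ self.wm1).T @ self.wm2).T
        return xm + mixed * self.gate(xm)


def pool_interaction(y: Tensor) -> Tensor:
    """Global average pooling along both axes, concatenated:
    ``(B, N, C) -> (B, N + C)``."""
    y = as_tensor(y)
    squeeze = y.ndim == 2
    if squeeze:
        y = y.reshape(1, *y.shape)
    v = concat([y.mean(axis=2), y.mean(axis=1)], axis=1)
    return v.reshape(v.shape[1]) if squeeze else v


class AffinityHead(Module):
    """Three fully-connected layers with rectifiers and dropout → scalar."""

    def __init__(self, in_dim: int, hidden: tuple[int, int], dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        h1, h2 = hidden
        self.fc1 = Linear(in_dim, h1, rng)
        self.fc2 = Linear(h1, h2, rng)
        self.fc3 = Linear(h2, 1, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, v: Tensor) -> Tensor:
        h = self.drop1(self.fc1(v).relu())
        h = self.drop2(self.fc2(h).relu())
        return self.fc3(h)


class MixDecoder(Module):
    """Full decoder: returns (affinity prediction, response vector)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.sampler = DrugKernelSampler(cfg.l_d, cfg.c_s, rng)
        self.se_protein = SelfEnhance(cfg.c_s, rng)
        self.se_drug = SelfEnhance(cfg.c_s, rng)
        self.cross = CrossAttend(cfg.l_p + cfg.l_d, cfg.c_s, rng)
        self.head = AffinityHead(cfg.interaction_dim, cfg.head_hidden,
                                 cfg.dropout, rng)

    def forward(self, fp: Tensor, fd: Tensor,
                adj: np.ndarray) -> tuple[Tensor, Tensor]:
        kernel = self.sampler(fd)
        s = compute_response_vector(fp, kernel)
        xp = inject_region_info(fp, s)
        xd = inject_adj_info(fd, adj)
        y = self.cross(self.se_protein(xp), self.se_drug(xd))
        v = pool_interaction(y)
        return self.head(v).reshape(v.shape[0]), s
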