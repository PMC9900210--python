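"""Losses and binding-site label embedding.

The affinity task uses mean squared error. The per-residue binding-region
task uses a rectified Wing loss: exactly zero inside a dead zone around
zero, logarithmic in the mid range and linear in the tails, with the linear
offset chosen so the pieces join continuously.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np

from .config import LossConfig
from .data_io import merge_intervals
from .nn import Tensor, as_tensor

__all__ = [
    "mse_loss", "rwing", "rwing_tensor", "embed_site_labels", "joint_loss",
]


def mse_loss(pred, target) -> Tensor:
    pred = as_tensor(pred)
    target = as_tensor(target)
    if pred.data.size == 0:
        raise ValueError("mse_loss of empty input is undefined")
    return ((pred - target) ** 2).mean()


def _rwing_constant(p: LossConfig) -> float:
    # the unique offset making the linear tail continuous at |x| = w
    return p.w - p.w * math.log1p((p.w - p.r) / p.epsilon)


def rwing(x, params: LossConfig | None = None) -> np.ndarray | float:
    """Scalar/array rectified Wing loss (pure numpy, no autodiff)."""
    p = params or LossConfig()
    ax = np.abs(np.asarray(x, dtype=np.float64))
    c = _rwing_constant(p)
    safe = np.maximum(ax - p.r, 0.0)
    out = np.where(
        ax < p.r, 0.0,
        np.where(ax < p.w, p.w * np.log1p(safe / p.epsilon), ax - c))
    return out if out.shape else float(out)


def rwing_tensor(x: Tensor, params: LossConfig | None = None) -> Tensor:
    """Differentiable rectified Wing loss, elementwise on a Tensor.

    Branches are selected by constant masks of the input value; the gradient
    is exact everywhere except at the (measure-zero) branch boundaries.
    """
    p = params or LossConfig()
    ax = as_tensor(x).abs()
    dead = Tensor((ax.data < p.r).astype(np.float64))
    mid = Tensor(((ax.data >= p.r) & (ax.data < p.w)).astype(np.float64))
    tail = Tensor((ax.data >= p.w).astype(np.float64))
    c = _rwing_constant(p)
    # shift the log argument into its valid domain on masked-out entries
    safe = ax * mid + (1.0 - mid) * p.r
    mid_val = ((safe - p.r) / p.epsilon + 1.0).log() * p.w
    return mid * mid_val + tail * (ax - c) + dead * 0.0


def embed_site_labels(sites: Sequence[tuple[int, int]], affinity: float,
                      l_p: int) -> np.ndarray:
    """Zeros except the affinity value on annotated site residues.

    Intervals are merged first; parts beyond ``l_p`` (truncated sequences)
    are clipped away with a warning.
    """
    y = np.zeros(l_p)
    for start, end in merge_intervals(list(sites)):
        if start >= l_p:
            warnings.warn(
                f"site ({start}, {end}) beyond length budget {l_p}; dropped",
                stacklevel=2)
            continue
        if end > l_p:
            warnings.warn(
                f"site ({start}, {end}) clipped to ({start}, {l_p})",
                stacklevel=2)
        y[start:min(end, l_p)] = affinity
    return y


def joint_loss(pred_aff: Tensor, true_aff, s: Tensor, y,
               lambda_br: float = 1.0, params: LossConfig | None = None,
               site_mask=None) -> Tensor:
    """``MSE(affinity) + lambda * mean RWing(s - y)`` over the batch.

    ``site_mask`` (per-sample booleans) excludes pairs without site
    annotations from the region term.
    """
    loss = mse_loss(pred_aff, true_aff)
    if lambda_br == 0.0:
        return loss
    s = as_tensor(s)
    y = as_tensor(y)
    resid = rwing_tensor(s - y, params)
    per_sample = resid.mean(axis=-1)
    if site_mask is not None:
        mask = np.asarray(site_mask, dtype=np.float64)
        if mask.sum() == 0:
            return loss
        per_sample = per_sample * Tensor(mask)
        return loss + lambda_br * per_sample.sum() / float(mask.sum())
    return loss + lambda_br * per_sample.mean()
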