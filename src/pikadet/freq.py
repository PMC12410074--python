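"""Frequency-domain feature machinery.

"Frequency" here is the spatial blur-residual decomposition, not a Fourier
transform: the low-frequency component of a feature map is its sliding-window
mean (boundary-truncated, so constants are reproduced exactly), and the
high-frequency component is the residual after subtracting it.  The
``FrequencyEnhancer`` adds a sigmoid-gated copy of that high-pass residual
back onto the input; ``MSFusionBlock`` applies pooled-and-enhanced processing
at several spatial fractions and fuses them; ``MSFusion`` runs one such block
per pyramid level and merges the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from . import nn
from .tensor import Tensor, concat


@dataclass
class ScaleSet:
    """Spatial fractions at which the multi-scale block operates."""

    fractions: tuple = (1.0, 0.5, 0.25)
    pool_kernel: int = 3

    def __post_init__(self):
        fr = tuple(self.fractions)
        if not fr or any(not (0 < f <= 1) for f in fr):
            raise ValueError("fractions must lie in (0, 1]")
        if len(set(fr)) != len(fr) or list(fr) != sorted(fr, reverse=True):
            raise ValueError("fractions must be distinct and descending")
        if self.pool_kernel < 3 or self.pool_kernel % 2 == 0:
            raise ValueError("pool_kernel must be odd and >= 3")
        self.fractions = fr


def extract_high(x: Tensor, pool_kernel: int) -> Tensor:
    """High-pass residual x - blur(x).

    The blur is a size-preserving sliding mean that averages in-bounds
    samples only, so a spatially constant input maps to exactly zero.
    """
    if pool_kernel % 2 == 0:
        raise ValueError("pool_kernel must be odd")
    return x - x.blur_mean(pool_kernel)


class FrequencyEnhancer(nn.Module):
    """x + sigmoid(conv1x1(high)) * high, with high = x - blur(x).

    The 1x1 convolution scores the high-pass residual and the logistic gate
    modulates how much of it is added back.  On constant inputs high == 0, so
    the module is exactly the identity regardless of its weights.
    """

    def __init__(self, c: int, pool_kernel: int = 3, rng=None):
        super().__init__()
        self.pool_kernel = pool_kernel
        self.gate = nn.Conv2d(c, c, 1, rng=rng)

    def forward(self, x):
        high = extract_high(x, self.pool_kernel)
        return x + self.gate(high).sigmoid() * high


def frequency_enhance(x: Tensor, pool_kernel: int, rng=None) -> Tensor:
    return FrequencyEnhancer(x.shape[1], pool_kernel,
                             rng=rng or np.random.default_rng(0))(x)


class MSFusionBlock(nn.Module):
    """Multi-scale pooled + frequency-enhanced feature block.

    For each fraction f: adaptive average-pool to (ceil(f*H), ceil(f*W)) ->
    3x3 conv -> 1x1 conv -> FrequencyEnhancer -> bilinear resize back to
    (H, W).  All scale branches plus the raw identity branch are concatenated
    and fused by a 1x1 convolution to ``out_channels``.

    ``branch_channels`` is the width of every scale branch; it is the free
    width that sets the block's capacity/cost trade-off.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 branch_channels: int | None = None,
                 scales: ScaleSet | None = None, rng=None):
        super().__init__()
        self.scales = scales or ScaleSet()
        w = branch_channels or max(8, in_channels // 4)
        self.branch_channels = w
        self.branches = nn.ModuleList()
        for _ in self.scales.fractions:
            self.branches.append(nn.Sequential([
                nn.ConvBNAct(in_channels, w, 3, rng=rng),
                nn.ConvBNAct(w, w, 1, rng=rng),
                FrequencyEnhancer(w, self.scales.pool_kernel, rng=rng),
            ]))
        fused_in = in_channels + w * len(self.scales.fractions)
        self.fuse = nn.ConvBNAct(fused_in, out_channels, 1, rng=rng)

    def forward(self, x):
        n, c, h, wd = x.shape
        outs = [x]
        for f, branch in zip(self.scales.fractions, self.branches):
            ph, pw = ceil(f * h), ceil(f * wd)
            if ph < 1 or pw < 1:
                raise ValueError(f"fraction {f} collapses a {h}x{wd} map to zero size")
            y = x if (ph, pw) == (h, wd) else x.adaptive_avg_pool(ph, pw)
            y = branch(y)
            if (ph, pw) != (h, wd):
                y = y.resize_bilinear(h, wd)
            outs.append(y)
        return self.fuse(concat(outs, axis=1))


class MSFusion(nn.Module):
    """Per-level MSFusionBlocks concatenated and fused to a target width.

    All input levels must already live on a common spatial grid (the neck
    upsamples before calling).
    """

    def __init__(self, in_channels: list, target_channels: int,
                 branch_channels: int | None = None,
                 scales: ScaleSet | None = None, rng=None):
        super().__init__()
        if not in_channels:
            raise ValueError("need at least one input level")
        self.blocks = nn.ModuleList([
            MSFusionBlock(c, target_channels, branch_channels, scales, rng=rng)
            for c in in_channels
        ])
        self.fuse = nn.ConvBNAct(target_channels * len(in_channels),
                                 target_channels, 1, rng=rng)

    def forward(self, levels):
        if len(levels) != len(self.blocks):
            raise ValueError(f"expected {len(self.blocks)} levels, got {len(levels)}")
        outs = [blk(x) for blk, x in zip(self.blocks, levels)]
        return self.fuse(concat(outs, axis=1))


def ms_fusion_block(x: Tensor, scales: ScaleSet, out_channels: int, rng=None) -> Tensor:
    return MSFusionBlock(x.shape[1], out_channels, scales=scales,
                         rng=rng or np.random.default_rng(0))(x)


def ms_fusion(levels, target_channels: int, rng=None) -> Tensor:
    if not levels:
        raise ValueError("empty level list")
    return MSFusion([x.shape[1] for x in levels], target_channels,
                    rng=rng or np.random.default_rng(0))(levels)
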