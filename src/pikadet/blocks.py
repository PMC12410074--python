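"""Backbone building blocks.

Two families live here.  The first is the standard nano-detector vocabulary:
``Bottleneck``/``C2f`` (split-transform-concatenate CSP blocks) and ``SPPF``
(cascaded max-pool spatial pyramid).  The second is the lightweight
replacement for C2f: a *star unit* that mixes features by elementwise
multiplication of two pointwise projections (an implicit lift into a
high-dimensional nonlinear feature space), a *gated attention unit* whose
multiplicative gate is computed per position from locally (depthwise-)
convolved features rather than from a global pooled summary, and the
``FusionBlock`` that wraps n repeats of (star unit -> gated unit) around a
50/50 channel split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .tensor import Tensor, concat


@dataclass
class BlockConfig:
    in_channels: int
    out_channels: int
    n_units: int = 1
    expansion: float = 3.0

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.expansion <= 0:
            raise ValueError("expansion must be > 0")


# ---------------------------------------------------------------------------
# baseline CSP vocabulary
# ---------------------------------------------------------------------------

class Bottleneck(nn.Module):
    def __init__(self, cin, cout, shortcut=True, e=0.5, rng=None):
        super().__init__()
        ch = int(cout * e)
        self.cv1 = nn.ConvBNAct(cin, ch, 3, rng=rng)
        self.cv2 = nn.ConvBNAct(ch, cout, 3, rng=rng)
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(nn.Module):
    """Split-transform-concatenate block with n inner bottlenecks."""

    def __init__(self, cin, cout, n=1, shortcut=False, e=0.5, rng=None):
        super().__init__()
        self.c = int(cout * e)
        self.cv1 = nn.ConvBNAct(cin, 2 * self.c, 1, rng=rng)
        self.cv2 = nn.ConvBNAct((2 + n) * self.c, cout, 1, rng=rng)
        self.m = nn.ModuleList([Bottleneck(self.c, self.c, shortcut, e=1.0, rng=rng)
                                for _ in range(n)])

    def forward(self, x):
        y = self.cv1(x)
        parts = [y.narrow(1, 0, self.c), y.narrow(1, self.c, self.c)]
        for m in self.m:
            parts.append(m(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class SPPF(nn.Module):
    def __init__(self, cin, cout, k=5, rng=None):
        super().__init__()
        ch = cin // 2
        self.k = k
        self.cv1 = nn.ConvBNAct(cin, ch, 1, rng=rng)
        self.cv2 = nn.ConvBNAct(ch * 4, cout, 1, rng=rng)

    def forward(self, x):
        x = self.cv1(x)
        y1 = x.maxpool2d(self.k, 1, self.k // 2)
        y2 = y1.maxpool2d(self.k, 1, self.k // 2)
        y3 = y2.maxpool2d(self.k, 1, self.k // 2)
        return self.cv2(concat([x, y1, y2, y3], axis=1))


# ---------------------------------------------------------------------------
# star / gated-attention fusion blocks
# ---------------------------------------------------------------------------

class StarUnit(nn.Module):
    """Residual star-operation mixer.

    depthwise 3x3 -> two parallel pointwise projections to expansion*C
    channels -> (bounded-rectifier branch) * (linear branch), elementwise ->
    pointwise projection back to C -> residual add.  The product of the two
    projections spans pairwise feature interactions, an implicit
    high-dimensional (kernel-like) feature map at pointwise-conv cost.
    """

    def __init__(self, c: int, expansion: float = 3.0, rng=None):
        super().__init__()
        hidden = int(round(c * expansion))
        self.dw = nn.ConvBNAct(c, c, 3, groups=c, act="none", rng=rng)
        self.f1 = nn.Conv2d(c, hidden, 1, rng=rng)
        self.f2 = nn.Conv2d(c, hidden, 1, rng=rng)
        self.proj = nn.Conv2d(hidden, c, 1, rng=rng)

    def forward(self, x):
        y = self.dw(x)
        y = self.f1(y).relu6() * self.f2(y)
        return x + self.proj(y)


class GatedAttentionUnit(nn.Module):
    """Fine-grained multiplicative gating.

    Two pointwise projections multiplied elementwise; the gate branch passes
    through a depthwise 3x3 before the logistic activation, so every spatial
    position receives its own gating signal from its local neighbourhood —
    unlike a global-average-pooled (squeeze-excite style) gate, which is
    constant over positions.
    """

    def __init__(self, c: int, rng=None):
        super().__init__()
        self.value = nn.Conv2d(c, c, 1, rng=rng)
        self.gate_pw = nn.Conv2d(c, c, 1, rng=rng)
        self.gate_dw = nn.Conv2d(c, c, 3, groups=c, rng=rng)
        self.proj = nn.Conv2d(c, c, 1, rng=rng)

    def gate_map(self, x: Tensor) -> Tensor:
        return self.gate_dw(self.gate_pw(x)).sigmoid()

    def forward(self, x):
        return x + self.proj(self.gate_map(x) * self.value(x))


class FusionModule(nn.Module):
    """n_units sequential repeats of (star unit -> gated attention unit)."""

    def __init__(self, c: int, n_units: int = 1, expansion: float = 3.0, rng=None):
        super().__init__()
        units = []
        for _ in range(n_units):
            units.append(StarUnit(c, expansion, rng=rng))
            units.append(GatedAttentionUnit(c, rng=rng))
        self.units = nn.Sequential(units)

    def forward(self, x):
        return self.units(x)


class FusionBlock(nn.Module):
    """C2f replacement: 1x1 conv to a hidden width, 50/50 split, one half
    through the FusionModule, the untouched half carried through, concat,
    1x1 fuse conv."""

    def __init__(self, cfg: BlockConfig, rng=None):
        super().__init__()
        hidden = cfg.in_channels
        if hidden % 2:
            raise ValueError(f"hidden width {hidden} is odd; the split must be exact")
        self.half = hidden // 2
        self.cv1 = nn.ConvBNAct(cfg.in_channels, hidden, 1, rng=rng)
        self.fusion = FusionModule(self.half, cfg.n_units, cfg.expansion, rng=rng)
        self.cv2 = nn.ConvBNAct(hidden, cfg.out_channels, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        a = y.narrow(1, 0, self.half)
        b = y.narrow(1, self.half, self.half)
        return self.cv2(concat([self.fusion(a), b], axis=1))


# -- functional wrappers matching the operation-level contracts --------------

def star_unit(x: Tensor, cfg: BlockConfig, rng=None) -> Tensor:
    if x.shape[1] != cfg.in_channels:
        raise ValueError(f"expected {cfg.in_channels} channels, got {x.shape[1]}")
    return StarUnit(cfg.in_channels, cfg.expansion,
                    rng=rng or np.random.default_rng(0))(x)


def gated_attention_unit(x: Tensor, rng=None) -> Tensor:
    return GatedAttentionUnit(x.shape[1], rng=rng or np.random.default_rng(0))(x)


def fusion_block(x: Tensor, cfg: BlockConfig, rng=None) -> Tensor:
    if x.shape[1] != cfg.in_channels:
        raise ValueError(f"expected {cfg.in_channels} channels, got {x.shape[1]}")
    return FusionBlock(cfg, rng=rng or np.random.default_rng(0))(x)
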