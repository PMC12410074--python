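"""Layer/module abstractions over the autodiff engine.

`Module` keeps an ordered registry of parameters and sub-modules (attribute
assignment registers automatically, like the major frameworks), so parameter
enumeration, seeding and optimizer steps are generic.  `ConvBNAct` is the
workhorse: convolution + per-channel batch normalization + activation, the
convention of the baseline one-stage detector family.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------
    def parameters(self) -> Iterator[Parameter]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for n, p in self._params.items():
            yield (f"{prefix}{n}", p)
        for n, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{n}.")

    def named_modules(self, prefix: str = "") -> Iterator[tuple]:
        yield (prefix.rstrip("."), self)
        for n, m in self._modules.items():
            yield from m.named_modules(f"{prefix}{n}.")

    def modules(self) -> Iterator["Module"]:
        for _, m in self.named_modules():
            yield m

    def get_module(self, name: str) -> "Module":
        for n, m in self.named_modules():
            if n == name:
                return m
        raise KeyError(f"no module named {name!r}")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict:
        out = {n: p.data.copy() for n, p in self.named_parameters()}
        for n, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{n}." if n else ""
                out[f"{key}running_mean"] = m.running_mean.copy()
                out[f"{key}running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, sd: dict):
        for n, p in self.named_parameters():
            p.data = np.asarray(sd[n], dtype=np.float32).reshape(p.data.shape)
        for n, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{n}." if n else ""
                m.running_mean = np.asarray(sd[f"{key}running_mean"], dtype=np.float32)
                m.running_var = np.asarray(sd[f"{key}running_var"], dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._items = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._items))] = m
        self._items.append(m)
        return self

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._items:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """Bare convolution.  Kaiming-uniform init from the module's local RNG
    stream so that two builds from the same seed are bit-identical."""

    def __init__(self, cin: int, cout: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = cin // groups * k * k
        bound = math.sqrt(1.0 / fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (cout, cin // groups, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            return self._train_forward(x)
        xc = x - Tensor(self.running_mean[None, :, None, None])
        inv = Tensor((1.0 / np.sqrt(self.running_var + self.eps))[None, :, None, None])
        w = self.weight.reshape(1, self.c, 1, 1)
        b = self.bias.reshape(1, self.c, 1, 1)
        return xc * inv * w + b

    def _train_forward(self, x: Tensor) -> Tensor:
        """Batch-statistics normalization with the exact backward (gradient
        flows through the batch mean and variance as well)."""
        axes = (0, 2, 3)
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        self.running_mean += self.momentum * (mu - self.running_mean)
        self.running_var += self.momentum * (var * n / max(n - 1, 1) - self.running_var)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out_data = xhat * self.weight.data[None, :, None, None] \
            + self.bias.data[None, :, None, None]
        weight, bias = self.weight, self.bias

        def backward(g):
            if bias.requires_grad:
                bias._accum(g.sum(axis=axes))
            if weight.requires_grad:
                weight._accum((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gx = g * weight.data[None, :, None, None]
                m1 = gx.mean(axis=axes)
                m2 = (gx * xhat).mean(axis=axes)
                dx = inv[None, :, None, None] * (
                    gx - m1[None, :, None, None] - xhat * m2[None, :, None, None])
                x._accum(dx.astype(np.float32))

        return x._node(out_data.astype(np.float32), (x, weight, bias), backward)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU6(Module):
    def forward(self, x):
        return x.relu6()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class ConvBNAct(Module):
    """Conv2d (no bias) + BatchNorm2d + activation — the detector's standard
    convolution unit."""

    def __init__(self, cin, cout, k=1, stride=1, padding=None, groups=1,
                 act: str = "silu", rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, padding, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = {"silu": SiLU, "relu6": ReLU6, "none": Identity}[act]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Upsample2x(Module):
    def forward(self, x):
        return x.upsample_nearest(2)


# ---------------------------------------------------------------------------
# parameter accounting helpers
# ---------------------------------------------------------------------------

def count_scalars(module: Module, convention: str = "all") -> int:
    """Number of learnable scalars.

    convention="all": every learnable tensor.
    convention="conv_affine": convolution/affine weights and biases only —
    normalization affine vectors excluded, matching the complexity-accounting
    convention used for the reported model sizes (normalization folds into the
    preceding convolution at deployment).
    """
    if convention == "all":
        return sum(p.size for p in module.parameters())
    if convention == "conv_affine":
        total = 0
        for m in module.modules():
            if isinstance(m, Conv2d):
                total += m.weight.size + (m.bias.size if m.bias is not None else 0)
        return total
    raise ValueError(f"unknown convention {convention!r}")
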