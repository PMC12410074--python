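"""Parameter and multiply-accumulate accounting.

Conventions (stated once, used everywhere):

* reported parameter counts cover convolution/affine weights and biases only,
  i.e. the deploy-time graph with normalization folded away; `count_params`
  with the default convention instead returns every learnable scalar;
* MACs are counted for convolution/affine layers only (normalization,
  activations and elementwise ops excluded): a convolution contributes
  k^2 * Cin/groups * Cout * Hout * Wout multiply-accumulates;
* GFLOPs = 2 x MACs / 1e9 at the stated input resolution;
* reported rounding: parameters to 2 decimals in millions, GFLOPs to 1
  decimal, mirroring the usual model-size tables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

# MAC recording hook used by the conv op. ``_ACTIVE`` is a list while a
# profiled forward pass runs, else None.
_ACTIVE: list | None = None


def _record_conv(cin, cout, k2, groups, ho, wo, n):
    _ACTIVE.append(k2 * (cin // groups) * cout * ho * wo * n)


@dataclass
class ProfileReport:
    variant: str
    params_million: float
    gflops: float
    input_size: int
    num_classes: int
    params_exact: int
    macs_exact: int

    def as_dict(self):
        return asdict(self)


def count_params(model, convention: str = "all") -> int:
    """Exact number of learnable scalars in a built model."""
    from .nn import count_scalars
    return count_scalars(model, convention)


def count_macs(model, input_size: int) -> int:
    """Multiply-accumulates of one forward pass at ``input_size`` square input."""
    global _ACTIVE
    from .tensor import Tensor, no_grad
    was_training = model.training
    model.eval()
    _ACTIVE = []
    try:
        with no_grad():
            model(Tensor(np.zeros((1, 3, input_size, input_size), dtype=np.float32)))
        macs = int(sum(_ACTIVE))
    finally:
        _ACTIVE = None
        model.train(was_training)
    return macs


def gflops(model, input_size: int) -> float:
    return 2.0 * count_macs(model, input_size) / 1e9


def profile_model(model, variant: str, num_classes: int, input_size: int = 640) -> ProfileReport:
    p = count_params(model, convention="conv_affine")
    m = count_macs(model, input_size)
    return ProfileReport(
        variant=variant,
        params_million=round(p / 1e6, 2),
        gflops=round(2.0 * m / 1e9, 1),
        input_size=input_size,
        num_classes=num_classes,
        params_exact=p,
        macs_exact=m,
    )


def profile_table(specs) -> list[ProfileReport]:
    """One report per model spec (the machine-readable complexity table)."""
    from .models import build_model
    reports = []
    for spec in specs:
        model = build_model(spec)
        reports.append(profile_model(model, spec.variant, spec.num_classes, spec.input_size))
    return reports
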