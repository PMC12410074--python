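"""High-pass extraction and the frequency-enhanced multi-scale blocks:
loop oracles, exact identities, energy ordering and dimension bookkeeping."""

import numpy as np
import pytest

from pikadet.freq import (FrequencyEnhancer, MSFusion, MSFusionBlock, ScaleSet,
                          extract_high, frequency_enhance)
from pikadet.tensor import Tensor


def loop_blur(x: np.ndarray, k: int) -> np.ndarray:
    """Brute-force sliding mean over in-bounds samples only."""
    r = k // 2
    out = np.zeros_like(x)
    n, c, h, w = x.shape
    for ni in range(n):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    patch = x[ni, ci, max(i - r, 0):min(i + r + 1, h),
                              max(j - r, 0):min(j + r + 1, w)]
                    out[ni, ci, i, j] = patch.mean()
    return out


def test_constant_input_has_zero_high_frequency():
    x = Tensor(np.full((1, 3, 8, 8), 5.0, dtype="f4"))
    for k in (3, 5, 7):
        assert np.array_equal(extract_high(x, k).data, np.zeros((1, 3, 8, 8), "f4"))


def test_extract_high_matches_loop_oracle_on_ramp():
    ramp = np.arange(16, dtype="f4").reshape(1, 1, 4, 4)
    got = extract_high(Tensor(ramp), 3).data
    ref = ramp - loop_blur(ramp, 3)
    assert np.allclose(got, ref, atol=1e-6)


def test_extract_high_is_linear(rng):
    x = rng.normal(size=(1, 2, 7, 9)).astype("f4")
    one = extract_high(Tensor(x), 3).data
    two = extract_high(Tensor(2 * x), 3).data
    assert np.allclose(two, 2 * one, atol=1e-5)


def test_even_kernel_rejected():
    with pytest.raises(ValueError, match="odd"):
        extract_high(Tensor(np.zeros((1, 1, 4, 4), "f4")), 4)


def test_enhancer_is_identity_on_constants(rng):
    enh = FrequencyEnhancer(3, 3, rng=rng)
    x = Tensor(np.full((1, 3, 6, 6), -2.5, dtype="f4"))
    assert np.array_equal(enh(x).data, x.data)


def test_enhancer_half_gate_closed_form():
    """Zero gate weights -> sigmoid(0) = 1/2 -> output = x + high/2."""
    enh = FrequencyEnhancer(1, 3)
    enh.gate.weight.data[:] = 0.0
    enh.gate.bias.data[:] = 0.0
    ramp = np.arange(16, dtype="f4").reshape(1, 1, 4, 4)
    high = ramp - loop_blur(ramp, 3)
    assert np.allclose(enh(Tensor(ramp)).data, ramp + 0.5 * high, atol=1e-6)


def test_enhancer_shape_contract(rng):
    enh = FrequencyEnhancer(8, 3, rng=rng)
    x = Tensor(rng.normal(size=(1, 8, 13, 17)).astype("f4"))
    assert enh(x).shape == (1, 8, 13, 17)


def test_high_pass_energy_ordering(rng):
    """White noise carries more high-pass energy than its own blurred copy."""
    wins = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        x = Tensor(r.normal(size=(1, 1, 16, 16)).astype("f4"))
        blurred = x.blur_mean(3)
        e_noise = np.abs(extract_high(x, 3).data).mean()
        e_blur = np.abs(extract_high(blurred, 3).data).mean()
        wins += e_noise > e_blur
    assert wins == 10


def test_scale_set_validation():
    with pytest.raises(ValueError):
        ScaleSet(fractions=(0.5, 1.0))          # not descending
    with pytest.raises(ValueError):
        ScaleSet(fractions=(1.0, 1.0))          # not distinct
    with pytest.raises(ValueError):
        ScaleSet(pool_kernel=4)


def test_ms_block_degenerate_single_scale(rng):
    blk = MSFusionBlock(8, 12, scales=ScaleSet(fractions=(1.0,)), rng=rng)
    x = Tensor(rng.normal(size=(1, 8, 10, 10)).astype("f4"))
    assert blk(x).shape == (1, 12, 10, 10)


def test_ms_block_dimension_bookkeeping(rng):
    blk = MSFusionBlock(16, 24, branch_channels=8, rng=rng)
    x = Tensor(rng.normal(size=(1, 16, 32, 32)).astype("f4"))
    assert blk(x).shape == (1, 24, 32, 32)
    # internal pooled sizes follow ceil(f * H)
    from pikadet.tensor import _adaptive_matrix
    assert _adaptive_matrix(32, 16).shape == (16, 32)
    assert _adaptive_matrix(32, 8).shape == (8, 32)


@pytest.mark.parametrize("hw", [(9, 9), (13, 21)])
def test_ms_block_resize_round_trip(rng, hw):
    blk = MSFusionBlock(4, 4, branch_channels=4,
                        scales=ScaleSet(fractions=(1.0, 0.5, 0.25)), rng=rng)
    x = Tensor(rng.normal(size=(1, 4, *hw)).astype("f4"))
    assert blk(x).shape[2:] == hw


def test_ms_block_parameter_enumeration(rng):
    cin, cout, w = 16, 24, 8
    blk = MSFusionBlock(cin, cout, branch_channels=w, rng=rng)
    conv_bn = lambda a, b, k: k * k * a * b + 2 * b
    per_branch = conv_bn(cin, w, 3) + conv_bn(w, w, 1) + (w * w + w)  # + gate conv
    expected = 3 * per_branch + conv_bn(cin + 3 * w, cout, 1)
    assert sum(p.size for p in blk.parameters()) == expected


def test_ms_fusion_shape_and_dead_fuse(rng):
    fu = MSFusion([8, 8], 12, branch_channels=4, rng=rng)
    fu.eval()
    x = Tensor(rng.normal(size=(1, 8, 10, 10)).astype("f4"))
    out = fu([x, x])
    assert out.shape == (1, 12, 10, 10)
    # dead fuse conv: zero weights, bias vector b -> constant output b
    fu.fuse.conv.weight.data[:] = 0.0
    b = np.linspace(-1, 1, 12).astype("f4")
    fu.fuse.bn.bias.data[:] = b
    out = fu([x, x]).data
    expected = b * (0.5 * (1 + np.tanh(0.5 * b)))   # silu applied after the norm bias
    assert np.allclose(out, expected[None, :, None, None] * np.ones_like(out), atol=1e-5)


def test_ms_fusion_rejects_empty_levels():
    from pikadet.freq import ms_fusion
    with pytest.raises(ValueError, match="empty"):
        ms_fusion([], 8)
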