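"""Gradient-weighted class activation mapping.

The heatmap for a class is the positive part of the channel-weighted target
activation, the weight of each channel being the spatial mean of the class
score's gradient at that channel, upsampled to image resolution and min-max
normalized to [0, 1].  A score with zero gradient (e.g. a frozen constant
head) yields a uniform zero map via the guarded normalization.
"""

from __future__ import annotations

import numpy as np

from .models import DetectHead, Detector
from .tensor import Tensor, _bilinear_matrix


def grad_cam(model: Detector, image: np.ndarray, target_layer: str,
             class_id: int) -> np.ndarray:
    """Heatmap (H, W) in [0, 1] for ``class_id`` w.r.t. ``target_layer``."""
    if not 0 <= class_id < model.spec.num_classes:
        raise ValueError(f"class_id {class_id} out of range")
    layer = model.get_module(target_layer)   # KeyError if absent

    x = np.asarray(image, dtype=np.float32)
    if x.ndim == 3 and x.shape[2] == 3:
        x = x.transpose(2, 0, 1)
    if x.max() > 1.5:
        x = x / 255.0
    h_img, w_img = x.shape[-2:]

    captured = {}
    orig_forward = layer.forward

    def hooked(*args, **kwargs):
        out = orig_forward(*args, **kwargs)
        captured.setdefault("act", out)
        return out

    was_training = model.training
    model.eval()
    object.__setattr__(layer, "forward", hooked)
    try:
        inp = Tensor(x[None], requires_grad=True)
        raw = model(inp)
    finally:
        object.__setattr__(layer, "forward", orig_forward)
        model.train(was_training)
    if "act" not in captured:
        raise KeyError(f"layer {target_layer!r} was not reached in the forward pass")
    act = captured["act"]

    # class score: summed class logits over all cells and levels
    nc = model.spec.num_classes
    reg = 4 * DetectHead.REG_MAX
    score = None
    for lvl in raw:
        s = lvl.narrow(1, reg + class_id, 1).sum()
        score = s if score is None else score + s
    score.backward()

    a = act.data[0]
    g = act.grad[0] if act.grad is not None else np.zeros_like(a)
    weights = g.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * a).sum(axis=0), 0.0)
    ry = _bilinear_matrix(cam.shape[0], h_img)
    cx = _bilinear_matrix(cam.shape[1], w_img)
    cam = ry @ cam @ cx.T
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros((h_img, w_img), dtype=np.float32)
    return ((cam - lo) / (hi - lo)).astype(np.float32)
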