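"""Desk-scale training: target assignment, composite detection loss,
momentum-SGD with the one-cycle-style schedule, and evaluation.

The composite loss is the unmodified convention of the baseline head:
binary cross-entropy on per-class logits over every cell, complete-IoU on
decoded boxes at assigned cells, and a distribution-focal term on the box
bin logits (weights 0.5 / 7.5 / 1.5).  Cells are assigned to a ground truth
when their center lies inside its box, within a small radius of its center,
and the resulting offsets are representable by the bin range; ties go to the
smaller box.  This center-based assignment is a deliberate simplification of
the task-aligned assigner — adequate for overfitting-style property tests,
not tuned for large-scale accuracy.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import data as dataio
from .models import (DetectHead, Detector, ModelSpec, build_model, nms,
                     decode_predictions, save_checkpoint)
from .metrics import MatchSpec, ap_at, mean_ap, ap_by_scale, error_decomposition
from .tensor import Tensor, concat, maximum, minimum, no_grad

REG_MAX = DetectHead.REG_MAX


@dataclass
class TrainConfig:
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 0.0005
    warmup_epochs: float = 3.0
    epochs: int = 200
    batch: int = 32
    seed: int = 0
    img_size: int = 640
    augment: bool = False
    conf_threshold: float = 0.25
    iou_threshold: float = 0.5

    def __post_init__(self):
        if self.lr0 <= 0 or not (0 < self.lrf <= 1) or not (0 <= self.momentum < 1):
            raise ValueError("invalid optimizer hyperparameters")


def lr_schedule(epoch: float, cfg: TrainConfig) -> float:
    """Linear warmup to lr0 over warmup_epochs, then cosine decay to lr0*lrf."""
    if epoch < cfg.warmup_epochs:
        return cfg.lr0 * epoch / cfg.warmup_epochs
    final = cfg.lr0 * cfg.lrf
    t = min((epoch - cfg.warmup_epochs) / max(cfg.epochs - cfg.warmup_epochs, 1e-9), 1.0)
    return final + (cfg.lr0 - final) * 0.5 * (1.0 + math.cos(math.pi * t))


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

def assign_targets(gts_batch, strides, img_size: int, center_radius: float = 2.5):
    """Center-based assignment across pyramid levels.

    Returns (img_idx, anchor_idx, cls_ids, ltrb (K,4) in stride units,
    stride_per_pos, gt_boxes (K,4) px) over the flattened anchor list.
    """
    level_dims = [(img_size // s, s) for s in strides]
    offsets = np.cumsum([0] + [d * d for d, _ in level_dims])
    rows, cols, cls_ids, ltrb, strd, boxes = [], [], [], [], [], []
    for n, gts in enumerate(gts_batch):
        claimed = {}
        for g in sorted(gts, key=lambda g: -g.area):   # smaller boxes claim last -> win
            x1, y1, x2, y2 = g.box
            gcx, gcy = (x1 + x2) / 2, (y1 + y2) / 2
            for li, (dim, s) in enumerate(level_dims):
                ci0 = int(gcx // s)
                cj0 = int(gcy // s)
                for cj in range(max(cj0 - 1, 0), min(cj0 + 2, dim)):
                    for ci in range(max(ci0 - 1, 0), min(ci0 + 2, dim)):
                        px, py = (ci + 0.5) * s, (cj + 0.5) * s
                        if not (x1 <= px <= x2 and y1 <= py <= y2):
                            continue
                        if abs(px - gcx) > center_radius * s or abs(py - gcy) > center_radius * s:
                            continue
                        off = (px - x1, py - y1, x2 - px, y2 - py)
                        if max(off) / s > REG_MAX - 1.01:
                            continue
                        claimed[(li, cj, ci)] = (n, offsets[li] + cj * dim + ci,
                                                 g.class_id,
                                                 tuple(o / s for o in off), s, g.box)
        for key in claimed:
            n_, a_, c_, o_, s_, b_ = claimed[key]
            rows.append(n_)
            cols.append(a_)
            cls_ids.append(c_)
            ltrb.append(o_)
            strd.append(s_)
            boxes.append(b_)
    return (np.asarray(rows, dtype=int), np.asarray(cols, dtype=int),
            np.asarray(cls_ids, dtype=int),
            np.asarray(ltrb, dtype=np.float32).reshape(-1, 4),
            np.asarray(strd, dtype=np.float32),
            np.asarray(boxes, dtype=np.float32).reshape(-1, 4))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _bce_with_logits(x: Tensor, y: np.ndarray) -> Tensor:
    """Numerically stable elementwise binary cross-entropy (sum)."""
    return (x.clamp(lo=0.0) - x * Tensor(y) + ((-x.abs()).exp() + 1.0).log()).sum()


def _ciou(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Complete IoU between (K,4) predicted and constant ground-truth boxes."""
    g = Tensor(gt)
    px1, py1 = pred.narrow(1, 0, 1), pred.narrow(1, 1, 1)
    px2, py2 = pred.narrow(1, 2, 1), pred.narrow(1, 3, 1)
    gx1, gy1 = g.narrow(1, 0, 1), g.narrow(1, 1, 1)
    gx2, gy2 = g.narrow(1, 2, 1), g.narrow(1, 3, 1)
    iw = (minimum(px2, gx2) - maximum(px1, gx1)).clamp(lo=0.0)
    ih = (minimum(py2, gy2) - maximum(py1, gy1)).clamp(lo=0.0)
    inter = iw * ih
    pw, ph = (px2 - px1).clamp(lo=1e-6), (py2 - py1).clamp(lo=1e-6)
    gw, gh = gx2 - gx1, gy2 - gy1
    union = pw * ph + gw * gh - inter
    iou = inter / (union + 1e-7)
    # enclosing-box diagonal and center distance
    cw = maximum(px2, gx2) - minimum(px1, gx1)
    chh = maximum(py2, gy2) - minimum(py1, gy1)
    c2 = cw * cw + chh * chh + 1e-7
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2.0 + (py1 + py2 - gy1 - gy2) ** 2.0) * 0.25
    v = (gw / gh).atan() - (pw / ph).atan()
    v = v * v * (4.0 / math.pi ** 2)
    alpha = Tensor(v.data / np.maximum(1.0 - iou.data + v.data, 1e-7))  # detached
    return iou - rho2 / c2 - v * alpha


def detection_loss(raw_levels, gts_batch, num_classes: int, img_size: int,
                   strides=(8, 16, 32)):
    """Composite loss (scalar Tensor) + components dict."""
    n = raw_levels[0].shape[0]
    flat = concat([lvl.reshape(lvl.shape[0], lvl.shape[1],
                               lvl.shape[2] * lvl.shape[3])
                   for lvl in raw_levels], axis=2)          # (N, 4*REG+nc, A)
    rows, cols, cls_ids, ltrb, strd, gt_boxes = assign_targets(
        gts_batch, strides, img_size)
    total_anchors = flat.shape[2]
    n_pos = max(len(rows), 1)

    cls_logits = flat.narrow(1, 4 * REG_MAX, num_classes)
    targets = np.zeros((n, num_classes, total_anchors), dtype=np.float32)
    targets[rows, cls_ids, cols] = 1.0
    loss_cls = _bce_with_logits(cls_logits, targets) * (1.0 / n_pos)

    if len(rows):
        pos = flat.take_cells(rows, cols)                   # (K, 4*REG+nc)
        box_logits = pos.narrow(1, 0, 4 * REG_MAX).reshape(len(rows), 4, REG_MAX)
        # stable log-softmax (the focal term needs well-conditioned log-probs)
        mdet = Tensor(box_logits.data.max(axis=2, keepdims=True))
        shifted = box_logits - mdet
        logp = shifted - shifted.exp().sum(axis=2, keepdims=True).log()
        prob = logp.exp()
        bins = Tensor(np.arange(REG_MAX, dtype=np.float32)[None, None, :])
        dist = (prob * bins).sum(axis=2)                    # (K, 4) stride units
        # anchor centers in px
        centers = _anchor_centers(strides, img_size)
        cx = centers[cols, 0][:, None]
        cy = centers[cols, 1][:, None]
        sv = strd[:, None]
        l = dist.narrow(1, 0, 1) * sv
        t = dist.narrow(1, 1, 1) * sv
        r = dist.narrow(1, 2, 1) * sv
        b = dist.narrow(1, 3, 1) * sv
        pred_boxes = concat([Tensor(cx) - l, Tensor(cy) - t,
                             Tensor(cx) + r, Tensor(cy) + b], axis=1)
        loss_box = ((1.0 - _ciou(pred_boxes, gt_boxes)).sum()) * (1.0 / n_pos)

        # distribution-focal: cross-entropy split across the two flanking bins
        tgt = np.clip(ltrb, 0, REG_MAX - 1 - 1e-3)
        lo = np.floor(tgt).astype(int)
        hi = lo + 1
        w_hi = (tgt - lo).astype(np.float32)
        w_lo = 1.0 - w_hi
        onehot = np.zeros((len(rows), 4, REG_MAX), dtype=np.float32)
        k_idx = np.arange(len(rows))[:, None]
        s_idx = np.arange(4)[None, :]
        onehot[k_idx, s_idx, lo] += w_lo
        onehot[k_idx, s_idx, np.minimum(hi, REG_MAX - 1)] += w_hi
        loss_dfl = -(logp * Tensor(onehot)).sum() * (1.0 / (4 * n_pos))
    else:
        loss_box = Tensor(0.0)
        loss_dfl = Tensor(0.0)

    total = loss_cls * 0.5 + loss_box * 7.5 + loss_dfl * 1.5
    parts = {"cls": float(loss_cls.data), "box": float(loss_box.data),
             "dfl": float(loss_dfl.data), "total": float(total.data),
             "n_pos": int(len(rows))}
    return total, parts


_CENTER_CACHE = {}


def _anchor_centers(strides, img_size):
    key = (tuple(strides), img_size)
    if key not in _CENTER_CACHE:
        cs = []
        for s in strides:
            dim = img_size // s
            jj, ii = np.divmod(np.arange(dim * dim), dim)
            cs.append(np.stack([(ii + 0.5) * s, (jj + 0.5) * s], axis=1))
        _CENTER_CACHE[key] = np.concatenate(cs).astype(np.float32)
    return _CENTER_CACHE[key]


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class SGD:
    """Momentum SGD; weight decay applied to convolution kernels only."""

    def __init__(self, model, cfg: TrainConfig):
        self.params = list(model.parameters())
        self.cfg = cfg
        self.buf = [np.zeros_like(p.data) for p in self.params]
        self.lr = cfg.lr0

    def step(self):
        for p, v in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            if p.data.ndim >= 2 and self.cfg.weight_decay:
                g = g + self.cfg.weight_decay * p.data
            v *= self.cfg.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# training / evaluation loops
# ---------------------------------------------------------------------------

def _prepare_batch(images):
    x = np.stack([im.transpose(2, 0, 1) for im in images]).astype(np.float32) / 255.0
    return Tensor(x)


def _augment_batch(images, gts_batch, rng):
    out_im, out_gt = [], []
    for im, gts in zip(images, gts_batch):
        im = im.copy()
        if rng.random() < 0.5:   # horizontal flip
            W = im.shape[1]
            im = im[:, ::-1].copy()
            gts = [type(g)((W - g.box[2], g.box[1], W - g.box[0], g.box[3]),
                           g.class_id) for g in gts]
        gain = rng.uniform(0.9, 1.1)
        im = np.clip(im.astype(np.float32) * gain, 0, 255).astype(np.uint8)
        out_im.append(im)
        out_gt.append(gts)
    return out_im, out_gt


def train(model: Detector, dataset_manifest, cfg: TrainConfig,
          out_dir=None, log_fn=None):
    """Momentum-SGD training over the manifest's train split.

    Returns the per-epoch metric log; writes last/best checkpoints and a
    JSONL log when ``out_dir`` is given.  Fully deterministic given
    (seed, config, data).
    """
    manifest = dataio.load_manifest(dataset_manifest)
    samples = list(dataio.load_split(manifest, "train", cfg.img_size))
    if not samples:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model, cfg)
    model.train()
    history = []
    best = math.inf
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    n_batches = max(1, math.ceil(len(samples) / cfg.batch))
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(samples))
        epoch_loss, parts_acc = 0.0, None
        for bi in range(n_batches):
            idx = order[bi * cfg.batch:(bi + 1) * cfg.batch]
            if len(idx) == 0:
                continue
            images = [samples[i][0] for i in idx]
            gts = [samples[i][1] for i in idx]
            if cfg.augment:
                images, gts = _augment_batch(images, gts, rng)
            opt.lr = lr_schedule(epoch + bi / n_batches, cfg)
            opt.zero_grad()
            raw = model(_prepare_batch(images))
            loss, parts = detection_loss(raw, gts, model.spec.num_classes,
                                         cfg.img_size, model.spec.strides)
            loss.backward()
            opt.step()
            epoch_loss += parts["total"]
            parts_acc = parts
        rec = {"epoch": epoch, "loss": epoch_loss / n_batches,
               "lr": opt.lr, **{k: parts_acc[k] for k in ("cls", "box", "dfl")}}
        history.append(rec)
        if log_fn:
            log_fn(rec)
        if out:
            with open(out / "log.jsonl", "a") as f:
                f.write(json.dumps(rec) + "\n")
            save_checkpoint(model, out / "last.npz")
            if rec["loss"] < best:
                best = rec["loss"]
                save_checkpoint(model, out / "best.npz")
    return history


def predict_split(model: Detector, manifest: dict, split: str, cfg: TrainConfig):
    dets_pi, gts_pi = [], []
    was_training = model.training
    model.eval()
    for img, gts in dataio.load_split(manifest, split, cfg.img_size):
        with no_grad():
            raw = model(_prepare_batch([img]))
        dets = decode_predictions(raw, model.spec.strides, cfg.conf_threshold,
                                  model.spec.num_classes, cfg.img_size)
        dets_pi.append(nms(dets, cfg.iou_threshold))
        gts_pi.append(gts)
    model.train(was_training)
    return dets_pi, gts_pi


def evaluate(model_or_checkpoint, dataset_manifest, match_spec: MatchSpec | None = None,
             cfg: TrainConfig | None = None, split: str = "test") -> dict:
    """Inference + full metric report (JSON-serializable dict)."""
    from .models import load_checkpoint
    model = (model_or_checkpoint if isinstance(model_or_checkpoint, Detector)
             else load_checkpoint(model_or_checkpoint))
    cfg = cfg or TrainConfig()
    spec = match_spec or MatchSpec()
    manifest = dataio.load_manifest(dataset_manifest)
    if manifest.get("nc") not in (None, model.spec.num_classes):
        raise ValueError(
            f"manifest declares {manifest['nc']} classes, model has "
            f"{model.spec.num_classes}")
    dets_pi, gts_pi = predict_split(model, manifest, split, cfg)
    n_images = len(gts_pi)
    class_ids = sorted({g.class_id for gts in gts_pi for g in gts})
    if n_images == 0 or not class_ids:
        return {"split": split, "n_images": n_images, "per_class_ap50": {},
                "mAP50": None, "mAP50_95": None, "AP_S": None, "AP_M": None,
                "AP_L": None, "errors": None}
    per_cls = {c: round(ap_at(dets_pi, gts_pi, c, spec.iou_foreground), 6)
               for c in class_ids}
    m50, m5095 = mean_ap(dets_pi, gts_pi, class_ids)
    ap_s, ap_m, ap_l = ap_by_scale(dets_pi, gts_pi, spec, class_ids)
    errors = error_decomposition(dets_pi, gts_pi, spec)
    return {
        "split": split,
        "n_images": n_images,
        "per_class_ap50": per_cls,
        "mAP50": m50,
        "mAP50_95": m5095,
        "AP_S": ap_s, "AP_M": ap_m, "AP_L": ap_l,
        "errors": errors.as_dict(),
    }
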