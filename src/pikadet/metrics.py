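"""Detection metrics: precision/recall, interpolated AP, scale-stratified AP
and a six-way error decomposition.

Definitions.  P = TP/(TP+FP), R = TP/(TP+FN); AP is the area under the P(R)
sweep evaluated by 101-point interpolation (max precision at recalls 0.00,
0.01, ..., 1.00, averaged — the COCO convention); mAP50 averages AP over
classes at IoU 0.5, mAP50-95 additionally over IoU 0.50:0.05:0.95.  Scale
strata use the COCO area thresholds 32^2 / 96^2 px^2.

The error decomposition follows the TIDE scheme: every false positive is
attributed to exactly one of {classification, localization, both, duplicate,
background} using a foreground IoU threshold (default 0.5) and a background
IoU threshold (default 0.1); remaining unmatched ground truths are missed
detections.  Each category's magnitude is the mAP50 gain (in points) obtained
when an oracle fixes that category's errors alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .models import Detection, GroundTruthBox, box_iou


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PRCurve:
    points: list                # threshold-ordered (precision, recall) pairs
    class_id: int = 0


@dataclass
class MatchSpec:
    iou_foreground: float = 0.5
    iou_background: float = 0.1
    area_small: float = 32.0 ** 2
    area_medium: float = 96.0 ** 2

    def __post_init__(self):
        if not self.iou_background < self.iou_foreground:
            raise ValueError("iou_background must be < iou_foreground")


@dataclass
class ErrorBreakdown:
    Ecls: float = 0.0
    Eloc: float = 0.0
    Eboth: float = 0.0
    Edupe: float = 0.0
    Ebkg: float = 0.0
    Emiss: float = 0.0

    def as_dict(self):
        return {k: getattr(self, k) for k in
                ("Ecls", "Eloc", "Eboth", "Edupe", "Ebkg", "Emiss")}


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_detections(dets, gts, iou_threshold: float):
    """Greedy one-to-one matching by descending score.

    Returns (order, tp_flags, matched_gt) where ``order`` indexes ``dets``
    sorted by score, ``tp_flags[k]`` says whether the k-th ranked detection
    matched, ``matched_gt[k]`` is the ground-truth index (or -1), plus the
    set of unmatched ground-truth indices.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
    taken = [False] * len(gts)
    tp = np.zeros(len(dets), dtype=bool)
    matched = np.full(len(dets), -1, dtype=int)
    for k, di in enumerate(order):
        d = dets[di]
        best, best_iou = -1, iou_threshold
        for gi, g in enumerate(gts):
            if taken[gi] or g.class_id != d.class_id:
                continue
            iou = box_iou(d.box, g.box)
            if iou >= best_iou:
                best, best_iou = gi, iou
        if best >= 0:
            taken[best] = True
            tp[k] = True
            matched[k] = best
    unmatched = {gi for gi, t in enumerate(taken) if not t}
    return order, tp, matched, unmatched


def precision_recall(c: ConfusionCounts):
    """Eq. P = TP/(TP+FP), R = TP/(TP+FN); zero denominators define the
    metric as zero and emit a warning."""
    if c.TP + c.FP == 0:
        warnings.warn("precision undefined (TP+FP=0); defined as 0", RuntimeWarning)
        p = 0.0
    else:
        p = c.TP / (c.TP + c.FP)
    if c.TP + c.FN == 0:
        warnings.warn("recall undefined (TP+FN=0); defined as 0", RuntimeWarning)
        r = 0.0
    else:
        r = c.TP / (c.TP + c.FN)
    return p, r


# ---------------------------------------------------------------------------
# average precision
# ---------------------------------------------------------------------------

def pr_curve(dets_per_image, gts_per_image, class_id: int, iou_threshold: float) -> PRCurve:
    """Score-sweep precision/recall pairs for one class over a dataset."""
    scores, flags = [], []
    n_gt = 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        cd = [d for d in dets if d.class_id == class_id]
        cg = [g for g in gts if g.class_id == class_id]
        n_gt += len(cg)
        order, tp, _, _ = match_detections(cd, cg, iou_threshold)
        for k, di in enumerate(order):
            scores.append(cd[di].score)
            flags.append(bool(tp[k]))
    if not scores or n_gt == 0:
        return PRCurve([], class_id)
    idx = np.argsort(-np.asarray(scores), kind="stable")
    tp_c = np.cumsum(np.asarray(flags)[idx])
    fp_c = np.cumsum(~np.asarray(flags)[idx])
    prec = tp_c / (tp_c + fp_c)
    rec = tp_c / n_gt
    return PRCurve(list(zip(prec.tolist(), rec.tolist())), class_id)


def average_precision(curve: PRCurve) -> float:
    """101-point interpolated AP of a precision/recall sweep."""
    if not curve.points:
        return 0.0
    prec = np.asarray([p for p, _ in curve.points])
    rec = np.asarray([r for _, r in curve.points])
    # max precision to the right of each recall level
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = rec >= r - 1e-12
        ap += prec[mask].max() if mask.any() else 0.0
    return ap / 101.0


def ap_at(dets_per_image, gts_per_image, class_id, iou_threshold) -> float:
    return average_precision(pr_curve(dets_per_image, gts_per_image,
                                      class_id, iou_threshold))


def mean_ap(dets_per_image, gts_per_image, class_ids,
            iou_set=tuple(np.arange(0.5, 0.96, 0.05))):
    """(mAP50, mAP50-95) over the given classes."""
    ap50 = [ap_at(dets_per_image, gts_per_image, c, 0.5) for c in class_ids]
    ap_all = [ap_at(dets_per_image, gts_per_image, c, t)
              for c in class_ids for t in iou_set]
    return float(np.mean(ap50)), float(np.mean(ap_all))


def ap_by_scale(dets_per_image, gts_per_image, spec: MatchSpec, class_ids=None):
    """(AP_S, AP_M, AP_L) with COCO-style area stratification.

    Ground truths outside a stratum are ignored; detections that overlap an
    ignored ground truth (IoU >= foreground threshold, same class) are
    discarded rather than counted as false positives.  An empty stratum
    yields None.
    """
    if class_ids is None:
        class_ids = sorted({g.class_id for gts in gts_per_image for g in gts})
    bounds = [(0.0, spec.area_small), (spec.area_small, spec.area_medium),
              (spec.area_medium, float("inf"))]
    out = []
    for lo, hi in bounds:
        stratum_gts, stratum_dets = [], []
        n_in = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            keep_g = [g for g in gts if lo <= g.area < hi]
            ignore_g = [g for g in gts if not (lo <= g.area < hi)]
            n_in += len(keep_g)
            keep_d = [d for d in dets
                      if not any(g.class_id == d.class_id
                                 and box_iou(d.box, g.box) >= spec.iou_foreground
                                 for g in ignore_g)]
            stratum_gts.append(keep_g)
            stratum_dets.append(keep_d)
        if n_in == 0:
            out.append(None)
            continue
        aps = [ap_at(stratum_dets, stratum_gts, c, spec.iou_foreground)
               for c in class_ids
               if any(g.class_id == c for gts in stratum_gts for g in gts)]
        out.append(float(np.mean(aps)) if aps else None)
    return tuple(out)


# ---------------------------------------------------------------------------
# six-way error decomposition (TIDE scheme)
# ---------------------------------------------------------------------------

_CATEGORIES = ("Ecls", "Eloc", "Eboth", "Edupe", "Ebkg", "Emiss")


def _as_image_lists(dets, gts):
    if dets and isinstance(dets[0], Detection):
        return [dets], [gts]
    if not dets and (not gts or isinstance(gts[0], GroundTruthBox)):
        return [list(dets)], [list(gts)]
    return list(dets), list(gts)


def _classify_errors(dets, gts, spec: MatchSpec):
    """Per-image attribution: each unmatched detection to exactly one of the
    five FP categories, each never-matched ground truth to Emiss."""
    order, tp, matched, unmatched_gt = match_detections(dets, gts, spec.iou_foreground)
    errors = {}          # det index -> (category, gt index or -1)
    used_by_cls_loc = set()
    for k, di in enumerate(order):
        if tp[k]:
            continue
        d = dets[di]
        ious = [box_iou(d.box, g.box) for g in gts]
        best_same = max((v for v, g in zip(ious, gts) if g.class_id == d.class_id),
                        default=0.0)
        best_other = max((v for v, g in zip(ious, gts) if g.class_id != d.class_id),
                         default=0.0)
        if best_other >= spec.iou_foreground:
            gi = int(np.argmax([v if g.class_id != d.class_id else -1
                                for v, g in zip(ious, gts)]))
            errors[di] = ("Ecls", gi)
            used_by_cls_loc.add(gi)
        elif best_same >= spec.iou_background:
            gi = int(np.argmax([v if g.class_id == d.class_id else -1
                                for v, g in zip(ious, gts)]))
            if best_same >= spec.iou_foreground:
                errors[di] = ("Edupe", gi)       # its ground truth is already claimed
            else:
                errors[di] = ("Eloc", gi)
                used_by_cls_loc.add(gi)
        elif best_other >= spec.iou_background:
            gi = int(np.argmax([v if g.class_id != d.class_id else -1
                                for v, g in zip(ious, gts)]))
            errors[di] = ("Eboth", gi)
            used_by_cls_loc.add(gi)
        else:
            errors[di] = ("Ebkg", -1)
    missed = [gi for gi in unmatched_gt if gi not in used_by_cls_loc]
    return errors, missed


def _fixed_sets(dets, gts, errors, missed, category):
    """Apply the oracle fix for one category; returns (dets, gts)."""
    new_dets, new_gts = list(dets), list(gts)
    drop_d, drop_g = set(), set()
    for di, (cat, gi) in errors.items():
        if cat != category:
            continue
        d = dets[di]
        if cat == "Ecls":
            new_dets[di] = replace(d, class_id=gts[gi].class_id)
        elif cat == "Eloc":
            new_dets[di] = replace(d, box=gts[gi].box)
        elif cat == "Eboth":
            new_dets[di] = replace(d, box=gts[gi].box, class_id=gts[gi].class_id)
        elif cat in ("Edupe", "Ebkg"):
            drop_d.add(di)
    if category == "Emiss":
        drop_g.update(missed)
    dets_out = [d for i, d in enumerate(new_dets) if i not in drop_d]
    gts_out = [g for i, g in enumerate(new_gts) if i not in drop_g]
    return dets_out, gts_out


def error_decomposition(dets, gts, spec: MatchSpec | None = None) -> ErrorBreakdown:
    """Oracle fix-and-re-evaluate error magnitudes, in mAP50 points."""
    spec = spec or MatchSpec()
    dets_pi, gts_pi = _as_image_lists(dets, gts)
    class_ids = sorted({g.class_id for gts_ in gts_pi for g in gts_})
    if not class_ids:
        return ErrorBreakdown()
    per_image = [_classify_errors(d, g, spec) for d, g in zip(dets_pi, gts_pi)]
    base, _ = mean_ap(dets_pi, gts_pi, class_ids, iou_set=(spec.iou_foreground,))
    out = {}
    for cat in _CATEGORIES:
        fixed_d, fixed_g = [], []
        for (d, g), (errors, missed) in zip(zip(dets_pi, gts_pi), per_image):
            fd, fg = _fixed_sets(d, g, errors, missed, cat)
            fixed_d.append(fd)
            fixed_g.append(fg)
        fixed_ids = sorted({g.class_id for gts_ in fixed_g for g in gts_})
        if not fixed_ids:
            out[cat] = max(0.0, (100.0 - base * 100.0))
            continue
        fixed_map, _ = mean_ap(fixed_d, fixed_g, fixed_ids,
                               iou_set=(spec.iou_foreground,))
        out[cat] = max(0.0, (fixed_map - base) * 100.0)
    return ErrorBreakdown(**out)


def count_error_events(dets, gts, spec: MatchSpec | None = None) -> dict:
    """Number of error events per category (every FP lands in exactly one)."""
    spec = spec or MatchSpec()
    dets_pi, gts_pi = _as_image_lists(dets, gts)
    counts = {c: 0 for c in _CATEGORIES}
    n_fp = 0
    for d, g in zip(dets_pi, gts_pi):
        errors, missed = _classify_errors(d, g, spec)
        for cat, _ in errors.values():
            counts[cat] += 1
        counts["Emiss"] += len(missed)
        _, tp, _, _ = match_detections(d, g, spec.iou_foreground)
        n_fp += int((~tp).sum())
    assert sum(counts[c] for c in _CATEGORIES[:-1]) == n_fp
    return counts
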