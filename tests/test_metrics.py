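"""Matching, precision/recall, interpolated AP, scale strata, error
decomposition and Grad-CAM — each against an independent reference."""

import numpy as np
import pytest

from pikadet import nn
from pikadet.metrics import (ConfusionCounts, MatchSpec, PRCurve, ap_at,
                             ap_by_scale, average_precision, count_error_events,
                             error_decomposition, match_detections, mean_ap,
                             precision_recall, pr_curve)
from pikadet.models import Detection, GroundTruthBox, box_iou
from pikadet.tensor import Tensor


def D(x1, y1, x2, y2, score, cid=0):
    return Detection((x1, y1, x2, y2), score, cid)


def G(x1, y1, x2, y2, cid=0):
    return GroundTruthBox((x1, y1, x2, y2), cid)


def reference_greedy_match(dets, gts, thr):
    """Independent O(n^2) re-implementation of score-ordered greedy matching."""
    flags = {}
    taken = set()
    for di in sorted(range(len(dets)), key=lambda i: -dets[i].score):
        cand = [(box_iou(dets[di].box, g.box), gi) for gi, g in enumerate(gts)
                if gi not in taken and g.class_id == dets[di].class_id]
        cand = [(v, gi) for v, gi in cand if v >= thr]
        if cand:
            v, gi = max(cand)
            taken.add(gi)
            flags[di] = gi
    return flags


def test_matching_perfect_and_duplicate():
    gts = [G(0, 0, 10, 10), G(20, 20, 30, 30)]
    dets = [D(0, 0, 10, 10, 0.9), D(20, 20, 30, 30, 0.8)]
    _, tp, _, unmatched = match_detections(dets, gts, 0.5)
    assert tp.all() and not unmatched
    dets.append(D(0, 0, 10, 10, 0.7))
    _, tp, _, unmatched = match_detections(dets, gts, 0.5)
    assert tp.sum() == 2 and (~tp).sum() == 1


def test_matching_agrees_with_reference_on_random_layouts(rng):
    for trial in range(50):
        r = np.random.default_rng(trial)
        dets = []
        for _ in range(6):
            x1, y1 = r.uniform(0, 40, 2)
            w, h = r.uniform(4, 20, 2)
            dets.append(D(x1, y1, x1 + w, y1 + h, float(r.random()), int(r.integers(2))))
        gts = []
        for _ in range(4):
            x1, y1 = r.uniform(0, 40, 2)
            w, h = r.uniform(4, 20, 2)
            gts.append(G(x1, y1, x1 + w, y1 + h, int(r.integers(2))))
        order, tp, matched, _ = match_detections(dets, gts, 0.3)
        ref = reference_greedy_match(dets, gts, 0.3)
        got = {di: int(m) for di, t, m in zip(order, tp, matched) if t}
        assert got == ref


def test_precision_recall_arithmetic_and_degenerate():
    assert precision_recall(ConfusionCounts(8, 2, 2)) == (0.8, 0.8)
    with pytest.warns(RuntimeWarning):
        p, r = precision_recall(ConfusionCounts(0, 0, 5))
    assert (p, r) == (0.0, 0.0)
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0)


def test_swapping_fp_fn_swaps_p_and_r():
    p1, r1 = precision_recall(ConfusionCounts(6, 3, 1))
    p2, r2 = precision_recall(ConfusionCounts(6, 1, 3))
    assert (p1, r1) == (r2, p2)


def independent_101_point(scores, flags, n_gt):
    """Direct evaluation of the 101-term interpolated sum."""
    idx = np.argsort(-np.asarray(scores), kind="stable")
    tp = np.cumsum(np.asarray(flags)[idx])
    fp = np.cumsum(~np.asarray(flags)[idx])
    prec = tp / (tp + fp)
    rec = tp / n_gt
    total = 0.0
    for i in range(101):
        r = i / 100.0
        ps = [p for p, rr in zip(prec, rec) if rr >= r - 1e-12]
        total += max(ps) if ps else 0.0
    return total / 101.0


def test_ap_extremes():
    gts = [[G(0, 0, 10, 10)], [G(5, 5, 9, 9)]]
    perfect = [[D(0, 0, 10, 10, 0.9)], [D(5, 5, 9, 9, 0.8)]]
    assert ap_at(perfect, gts, 0, 0.5) == pytest.approx(1.0)
    wrong = [[D(50, 50, 60, 60, 0.9)], [D(70, 70, 80, 80, 0.8)]]
    assert ap_at(wrong, gts, 0, 0.5) == 0.0
    assert average_precision(PRCurve([])) == 0.0


def test_ap_matches_independent_summation_hand_case():
    """5 scored detections / 3 ground truths: hits at ranks 1, 3, 4."""
    gts = [[G(0, 0, 10, 10), G(20, 0, 30, 10), G(40, 0, 50, 10)]]
    dets = [[
        D(0, 0, 10, 10, 0.95),        # TP
        D(100, 100, 110, 110, 0.90),  # FP
        D(20, 0, 30, 10, 0.80),       # TP
        D(40, 0, 50, 10, 0.70),       # TP
        D(200, 200, 210, 210, 0.60),  # FP
    ]]
    got = ap_at(dets, gts, 0, 0.5)
    ref = independent_101_point(
        [0.95, 0.90, 0.80, 0.70, 0.60], [True, False, True, True, False], 3)
    assert got == pytest.approx(ref)
    assert ref == pytest.approx((34 * 1.0 + 33 * (3 / 4) + 34 * (3 / 4)) / 101)


def test_ap_never_decreases_when_removing_a_false_positive():
    gts = [[G(0, 0, 10, 10), G(20, 0, 30, 10)]]
    dets = [[D(0, 0, 10, 10, 0.9), D(100, 100, 110, 110, 0.85),
             D(20, 0, 30, 10, 0.8)]]
    with_fp = ap_at(dets, gts, 0, 0.5)
    without = ap_at([[dets[0][0], dets[0][2]]], gts, 0, 0.5)
    assert without >= with_fp


def test_mean_ap_class_averaging():
    gts = [[G(0, 0, 10, 10, 0), G(20, 0, 30, 10, 1)]]
    dets = [[D(0, 0, 10, 10, 0.9, 0), D(20, 0, 30, 10, 0.8, 1)]]
    m50, m5095 = mean_ap(dets, gts, [0, 1])
    assert m50 == pytest.approx(1.0)
    assert m5095 == pytest.approx(1.0)
    # class 1 undetected -> mean of 1.0 and 0.0
    m50, _ = mean_ap([[dets[0][0]]], gts, [0, 1])
    assert m50 == pytest.approx(0.5)


def test_ap_by_scale_strata():
    spec = MatchSpec()
    small = G(0, 0, 10, 10)          # area 100 < 32^2
    medium = G(20, 20, 60, 60)       # 1600
    large = G(100, 100, 250, 250)    # 22500 > 96^2
    gts = [[small, medium, large]]
    perfect = [[D(*small.box, 0.9), D(*medium.box, 0.8), D(*large.box, 0.85)]]
    assert ap_by_scale(perfect, gts, spec) == (1.0, 1.0, 1.0)
    # all-small dataset: medium/large strata undefined
    assert ap_by_scale([[D(*small.box, 0.9)]], [[small]], spec)[1:] == (None, None)
    # only the small target missed
    miss_small = [[D(*medium.box, 0.8), D(*large.box, 0.85)]]
    ap_s, ap_m, ap_l = ap_by_scale(miss_small, gts, spec)
    assert ap_s == 0.0 < 1.0 == ap_m == ap_l


def test_error_decomposition_perfect_is_zero():
    gts = [G(0, 0, 10, 10, 0), G(20, 20, 30, 30, 1)]
    dets = [D(0, 0, 10, 10, 0.9, 0), D(20, 20, 30, 30, 0.8, 1)]
    bd = error_decomposition(dets, gts)
    assert all(v == 0.0 for v in bd.as_dict().values())


def test_error_decomposition_lights_up_own_category():
    gts = [G(0, 0, 10, 10, 0), G(40, 40, 50, 50, 1)]
    perfect = [D(0, 0, 10, 10, 0.9, 0), D(40, 40, 50, 50, 0.9, 1)]

    # duplicate ranked between two true positives of its class, so it costs mAP
    gts2 = gts + [G(20, 0, 30, 10, 0)]
    dup = error_decomposition(
        perfect + [D(0, 0, 10, 10, 0.95, 0), D(20, 0, 30, 10, 0.85, 0)], gts2)
    assert dup.Edupe > 0 and dup.Ebkg == 0 and dup.Ecls == 0

    bkg = error_decomposition(perfect + [D(100, 100, 120, 120, 0.95, 0)], gts)
    assert bkg.Ebkg > 0
    assert bkg.Ecls == bkg.Eloc == bkg.Eboth == bkg.Edupe == bkg.Emiss == 0

    # shifted same-class box in the (0.1, 0.5) IoU band, its GT then unmatched
    loc = error_decomposition(
        [D(4, 4, 14, 14, 0.9, 0), D(40, 40, 50, 50, 0.9, 1)], gts)
    assert loc.Eloc > 0 and loc.Ebkg == 0 and loc.Ecls == 0

    # wrong class on top of a ground truth
    cls = error_decomposition(
        [D(0, 0, 10, 10, 0.9, 1), D(40, 40, 50, 50, 0.9, 1)], gts)
    assert cls.Ecls > 0 and cls.Eloc == 0

    miss = error_decomposition([perfect[0]], gts)
    assert miss.Emiss > 0 and miss.Ebkg == 0


def test_single_class_forces_ecls_eboth_zero(rng):
    for trial in range(10):
        r = np.random.default_rng(trial)
        gts, dets = [], []
        for _ in range(5):
            x1, y1 = r.uniform(0, 80, 2)
            w, h = r.uniform(5, 20, 2)
            gts.append(G(x1, y1, x1 + w, y1 + h, 0))
        for _ in range(7):
            x1, y1 = r.uniform(0, 80, 2)
            w, h = r.uniform(5, 20, 2)
            dets.append(D(x1, y1, x1 + w, y1 + h, float(r.random()), 0))
        bd = error_decomposition(dets, gts)
        assert bd.Ecls == 0.0 and bd.Eboth == 0.0


def test_every_error_event_lands_in_exactly_one_category(rng):
    for trial in range(20):
        r = np.random.default_rng(100 + trial)
        gts, dets = [], []
        for _ in range(4):
            x1, y1 = r.uniform(0, 60, 2)
            w, h = r.uniform(5, 25, 2)
            gts.append(G(x1, y1, x1 + w, y1 + h, int(r.integers(2))))
        for _ in range(8):
            x1, y1 = r.uniform(0, 60, 2)
            w, h = r.uniform(5, 25, 2)
            dets.append(D(x1, y1, x1 + w, y1 + h, float(r.random()), int(r.integers(2))))
        counts = count_error_events(dets, gts)   # internal exhaustiveness assert
        assert all(v >= 0 for v in counts.values())


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

class _ToyDetector(nn.Module):
    """Single-conv stand-in exposing the detector interface grad_cam needs."""

    def __init__(self, weight, bias):
        super().__init__()
        from pikadet.models import DetectHead, ModelSpec
        c_out = 4 * DetectHead.REG_MAX + 2
        self.conv = nn.Conv2d(3, c_out, 3, bias=True)
        self.conv.weight.data[:] = weight
        self.conv.bias.data[:] = bias
        self.spec = ModelSpec("baseline", num_classes=2)

    def forward(self, x):
        return [self.conv(x)]


def test_grad_cam_matches_hand_computation(rng):
    from pikadet.gradcam import grad_cam
    from pikadet.models import DetectHead
    c_out = 4 * DetectHead.REG_MAX + 2
    w = rng.normal(size=(c_out, 3, 3, 3)).astype("f4") * 0.2
    b = rng.normal(size=c_out).astype("f4")
    b[4 * DetectHead.REG_MAX] = 0.5      # keep part of the class-0 map positive
    model = _ToyDetector(w, b)
    img = (rng.random((8, 8, 3)) * 255).astype(np.uint8)

    heat = grad_cam(model, img, "conv", class_id=0)
    assert heat.shape == (8, 8) and heat.min() >= 0 and heat.max() <= 1

    # hand computation: score = sum of class-0 channel -> gradient is 1 on
    # that channel -> weights are one-hot -> cam = relu(activation[cls0])
    x = img.transpose(2, 0, 1)[None].astype("f4") / 255.0
    act = Tensor(x).conv2d(Tensor(w), Tensor(b), 1, 1, 1).data[0]
    cam = np.maximum(act[4 * DetectHead.REG_MAX], 0)
    lo, hi = cam.min(), cam.max()
    expected = (cam - lo) / (hi - lo)
    assert np.allclose(heat, expected, atol=1e-5)


def test_grad_cam_degenerate_constant_head(rng):
    from pikadet.gradcam import grad_cam
    from pikadet.models import DetectHead
    c_out = 4 * DetectHead.REG_MAX + 2
    model = _ToyDetector(np.zeros((c_out, 3, 3, 3), "f4"),
                         np.ones(c_out, "f4"))
    img = (rng.random((8, 8, 3)) * 255).astype(np.uint8)
    heat = grad_cam(model, img, "conv", class_id=1)
    assert np.array_equal(heat, np.zeros((8, 8), "f4"))


def test_grad_cam_missing_layer_raises(rng):
    from pikadet.gradcam import grad_cam
    model = _ToyDetector(np.zeros((66, 3, 3, 3), "f4"), np.zeros(66, "f4"))
    with pytest.raises(KeyError):
        grad_cam(model, (rng.random((8, 8, 3)) * 255).astype(np.uint8),
                 "nonexistent", 0)
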