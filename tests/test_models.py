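"""Model assembly: stride grids, variant monotonicity, deterministic builds,
decode arithmetic, NMS against a brute-force reference, checkpoints."""

import numpy as np
import pytest

from pikadet.models import (Detection, DetectHead, ModelSpec, box_iou,
                            build_model, decode_predictions, load_checkpoint,
                            nms, save_checkpoint)
from pikadet.profiling import count_params
from pikadet.tensor import Tensor, no_grad

REG = DetectHead.REG_MAX


@pytest.fixture(scope="module")
def small_input(request):
    r = np.random.default_rng(0)
    return Tensor(r.random((1, 3, 160, 160), dtype=np.float32))


@pytest.mark.parametrize("variant", ["baseline", "fusion_backbone",
                                     "msfusion_neck", "yolo_pika"])
def test_forward_emits_three_stride_grids(variant, small_input):
    model = build_model(ModelSpec(variant, num_classes=2)).eval()
    with no_grad():
        raw = model(small_input)
    assert [lvl.shape[2] for lvl in raw] == [20, 10, 5]      # strides 8/16/32
    nc = 2
    assert all(lvl.shape[1] == 4 * REG + nc for lvl in raw)


def test_neck_head_width_round_trip():
    for variant in ("baseline", "msfusion_neck", "yolo_pika"):
        model = build_model(ModelSpec(variant, num_classes=2))
        for feats_ch, branch in zip(model.neck.ch_out, model.head.box):
            assert branch[0].conv.cin == feats_ch


def test_parameter_monotonicity_across_variants():
    counts = {}
    for v in ("baseline", "fusion_backbone", "msfusion_neck", "yolo_pika"):
        counts[v] = count_params(build_model(ModelSpec(v, num_classes=2)))
    assert (counts["yolo_pika"] < counts["msfusion_neck"]
            < counts["fusion_backbone"] < counts["baseline"])


def test_build_determinism_bitwise():
    spec = ModelSpec("yolo_pika", num_classes=2, seed=7)
    a = build_model(spec)
    b = build_model(spec)
    for (na, pa), (nb, pb) in zip(a.named_parameters(), b.named_parameters()):
        assert na == nb
        assert pa.data.tobytes() == pb.data.tobytes()


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="unknown variant"):
        ModelSpec("resnet")
    with pytest.raises(ValueError):
        ModelSpec("baseline", input_size=100)     # not divisible by 32


def test_decode_delta_distribution_closed_form():
    """A cell whose bin logits peak at k on every side decodes to a box
    centred on (cell + 0.5) * stride with half-extent k * stride."""
    nc, stride, h = 2, 8, 8
    raw = np.zeros((1, 4 * REG + nc, h, h), dtype=np.float32)
    raw[0, 4 * REG:] = -20.0                      # everything below threshold
    ci, cj, k = 5, 3, 2
    for side in range(4):
        raw[0, side * REG + k, cj, ci] = 30.0     # delta distribution at bin k
    raw[0, 4 * REG, cj, ci] = 5.0                 # confident class 0
    dets = decode_predictions([raw], (stride,), 0.5, nc, 64)
    assert len(dets) == 1
    d = dets[0]
    cx, cy = (ci + 0.5) * stride, (cj + 0.5) * stride
    assert d.box == pytest.approx((cx - k * stride, cy - k * stride,
                                   cx + k * stride, cy + k * stride), abs=1e-3)
    assert d.class_id == 0


def test_decode_thresholding_and_clipping(rng):
    nc = 2
    raw = rng.normal(size=(1, 4 * REG + nc, 6, 6)).astype("f4") * 10
    dets = decode_predictions([raw], (8,), 0.25, nc, 48)
    for d in dets:
        assert 0 <= d.box[0] < d.box[2] <= 48
        assert 0 <= d.box[1] < d.box[3] <= 48
    raw[:, 4 * REG:] = -30.0
    assert decode_predictions([raw], (8,), 0.25, nc, 48) == []


def brute_force_nms(dets, thr):
    keep = []
    for cid in {d.class_id for d in dets}:
        group = sorted([d for d in dets if d.class_id == cid], key=lambda d: -d.score)
        removed = set()
        for i, d in enumerate(group):
            if i in removed:
                continue
            keep.append(d)
            for j in range(i + 1, len(group)):
                if j not in removed and box_iou(d.box, group[j].box) > thr:
                    removed.add(j)
    return keep


def test_nms_basics():
    one = [Detection((0, 0, 10, 10), 0.9, 0)]
    assert nms(one, 0.5) == one
    two = [Detection((0, 0, 10, 10), 0.9, 0), Detection((0, 0, 10, 10), 0.8, 0)]
    out = nms(two, 0.5)
    assert len(out) == 1 and out[0].score == 0.9


def test_nms_matches_brute_force_reference(rng):
    for trial in range(30):
        r = np.random.default_rng(trial)
        dets = []
        for _ in range(10):
            x1, y1 = r.uniform(0, 60, 2)
            w, h = r.uniform(5, 40, 2)
            dets.append(Detection((x1, y1, x1 + w, y1 + h),
                                  float(r.random()), int(r.integers(2))))
        got = nms(dets, 0.5)
        ref = brute_force_nms(dets, 0.5)
        assert sorted((d.box, d.score) for d in got) == \
            sorted((d.box, d.score) for d in ref)
        assert nms(got, 0.5) == got               # idempotence


def test_checkpoint_round_trip(tmp_path):
    spec = ModelSpec("baseline", num_classes=2, seed=3)
    model = build_model(spec)
    path = tmp_path / "w.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.spec == spec
    for (_, pa), (_, pb) in zip(model.named_parameters(), restored.named_parameters()):
        assert np.array_equal(pa.data, pb.data)


def test_single_optimization_step_decreases_loss(tiny_dataset):
    from pikadet.data import load_manifest, load_split
    from pikadet.train import SGD, TrainConfig, detection_loss, _prepare_batch

    manifest = load_manifest(tiny_dataset)
    img, gts = next(load_split(manifest, "train", 128))
    spec = ModelSpec("baseline", num_classes=2, seed=0)
    model = build_model(spec)
    cfg = TrainConfig(img_size=128)
    opt = SGD(model, cfg)
    opt.lr = 1e-4
    losses = []
    for _ in range(2):
        opt.zero_grad()
        raw = model(_prepare_batch([img]))
        loss, parts = detection_loss(raw, [gts], 2, 128, spec.strides)
        loss.backward()
        opt.step()
        losses.append(parts["total"])
    assert losses[1] < losses[0]
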