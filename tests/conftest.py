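import numpy as np
import pytest

from pikadet.models import Detection, GroundTruthBox
from pikadet.scenes import SceneConfig, render_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """8 small synthetic scenes as a rendered train-only dataset."""
    out = tmp_path_factory.mktemp("scenes")
    cfg = SceneConfig(image_size=128, seed=1)
    manifest = render_dataset(cfg, 8, out, split=(1.0, 0.0, 0.0))
    return manifest


def random_boxes(rng, n, size=100.0, classes=2):
    """Random well-formed detections and ground truths in a size x size frame."""
    dets, gts = [], []
    for _ in range(n):
        x1, y1 = rng.uniform(0, size * 0.7, 2)
        w, h = rng.uniform(5, size * 0.3, 2)
        cid = int(rng.integers(classes))
        if rng.random() < 0.5:
            dets.append(Detection((x1, y1, x1 + w, y1 + h), float(rng.random()), cid))
        else:
            gts.append(GroundTruthBox((x1, y1, x1 + w, y1 + h), cid))
    return dets, gts
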