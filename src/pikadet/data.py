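"""Dataset I/O: YOLO-format labels and YAML manifests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .models import GroundTruthBox


def read_yolo_labels(path) -> list:
    """Parse one `class cx cy w h` file into (class_id, cx, cy, w, h) tuples."""
    out = []
    text = Path(path).read_text() if Path(path).exists() else ""
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        out.append((int(parts[0]),) + tuple(float(v) for v in parts[1:5]))
    return out


def labels_to_gt(labels, image_size: int) -> list:
    """Normalized center-format labels -> pixel-coordinate ground-truth boxes."""
    gts = []
    for cid, cx, cy, w, h in labels:
        x1 = (cx - w / 2) * image_size
        y1 = (cy - h / 2) * image_size
        x2 = (cx + w / 2) * image_size
        y2 = (cy + h / 2) * image_size
        gts.append(GroundTruthBox((x1, y1, x2, y2), cid))
    return gts


def load_manifest(path) -> dict:
    m = yaml.safe_load(Path(path).read_text())
    m["_root"] = Path(path).resolve().parent
    return m


def list_split(manifest: dict, split: str) -> list:
    root = Path(manifest.get("path", manifest["_root"]))
    img_dir = root / manifest[split]
    return sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg"))


def label_path_for(image_path: Path) -> Path:
    parts = list(image_path.parts)
    parts[-3] = "labels"
    return Path(*parts).with_suffix(".txt")


def load_image(path, img_size: int | None = None) -> np.ndarray:
    im = Image.open(path).convert("RGB")
    if img_size is not None and im.size != (img_size, img_size):
        im = im.resize((img_size, img_size), Image.BILINEAR)
    return np.asarray(im, dtype=np.uint8)


def load_split(manifest: dict, split: str, img_size: int):
    """Yield (image array, ground-truth boxes at img_size) pairs."""
    for img_path in list_split(manifest, split):
        img = load_image(img_path, img_size)
        labels = read_yolo_labels(label_path_for(img_path))
        yield img, labels_to_gt(labels, img_size)
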