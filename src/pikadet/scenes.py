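"""Seeded synthetic aerial grassland scenes.

Emulates nadir UAV imagery of alpine meadow at ~15 m altitude: a multi-octave
value-noise grass texture mapped through a green-brown palette, with two
labeled target classes — burrow entrances (dark ellipses ringed by a lighter
excavated-soil rim) and dung (irregular brown blobs) — plus unlabeled
distractors (pale stones, soft shadows) that exercise the background
false-positive channel of the error decomposition.  The targets are small and
low-contrast against the background on purpose.

Conventions, stated once and used everywhere: labels are normalized
center-format ``class cx cy w h`` with six decimals, class 0 = burrow and
class 1 = dung; images are indexed from the top-left with pixel centers at
integer + 0.5.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

CLASS_NAMES = {0: "burrow", 1: "dung"}

#: palette anchors (RGB), green grass -> dry brown grass
_GRASS_GREEN = np.array([88, 112, 58], dtype=np.float32)
_GRASS_BROWN = np.array([132, 112, 74], dtype=np.float32)
_BURROW_DARK = np.array([32, 27, 22], dtype=np.float32)
_RIM_SOIL = np.array([150, 128, 96], dtype=np.float32)
_DUNG_BROWN = np.array([92, 68, 44], dtype=np.float32)
_STONE_GRAY = np.array([168, 166, 158], dtype=np.float32)


@dataclass
class SceneConfig:
    image_size: int = 640
    burrow_rate: float = 4.0          # expected burrows per image (Poisson)
    dung_rate: float = 2.0
    burrow_radius: tuple = (6.0, 14.0)   # px, semi-major axis range
    dung_radius: tuple = (4.0, 10.0)
    contrast: tuple = (0.55, 0.9)        # blend strength of targets vs background
    distractor_rate: float = 3.0         # stones/shadows per image, unlabeled
    texture_octaves: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for rate in (self.burrow_rate, self.dung_rate, self.distractor_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for lo, hi in (self.burrow_radius, self.dung_radius):
            if not (0 < lo <= hi):
                raise ValueError("radius ranges must be positive and ordered")
        if self.texture_octaves < 1:
            raise ValueError("texture_octaves must be >= 1")


@dataclass
class LabeledImage:
    pixels: np.ndarray                 # (H, W, 3) uint8
    labels: list = field(default_factory=list)   # (class_id, cx, cy, w, h) normalized


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def _value_noise(size: int, cells: int, rng: np.random.Generator) -> np.ndarray:
    """Bilinearly interpolated lattice noise in [0, 1]."""
    lattice = rng.random((cells + 1, cells + 1), dtype=np.float64)
    t = np.linspace(0, cells, size, endpoint=False)
    i = np.floor(t).astype(int)
    f = (t - i).astype(np.float64)
    a = lattice[np.ix_(i, i)]
    b = lattice[np.ix_(i, i + 1)]
    c = lattice[np.ix_(i + 1, i)]
    d = lattice[np.ix_(i + 1, i + 1)]
    fy, fx = f[:, None], f[None, :]
    return (a * (1 - fx) * (1 - fy) + b * fx * (1 - fy)
            + c * (1 - fx) * fy + d * fx * fy)


def generate_background(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Multi-octave grass texture as an (H, W, 3) uint8 array."""
    size = cfg.image_size
    field_ = np.zeros((size, size), dtype=np.float64)
    amp_total = 0.0
    for o in range(cfg.texture_octaves):
        cells = min(4 * 2 ** o, size // 2)
        amp = 0.55 ** o
        field_ += amp * _value_noise(size, cells, rng)
        amp_total += amp
    field_ /= amp_total
    img = _GRASS_GREEN[None, None] + field_[..., None] * (_GRASS_BROWN - _GRASS_GREEN)[None, None]
    # faint per-pixel blade speckle (kept well below the octave amplitudes so
    # the texture spectrum is governed by texture_octaves)
    img += rng.normal(0.0, 1.0, (size, size, 1))
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# object stamps
# ---------------------------------------------------------------------------

def _ellipse_mask(size, cx, cy, a, b, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx + 0.5) - cx
    y = (yy + 0.5) - cy
    ct, st = math.cos(theta), math.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return u * u + v * v


def _blob_mask(size, cx, cy, r0, rng):
    """Irregular star-convex blob: radius modulated by low-order harmonics."""
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx + 0.5) - cx
    y = (yy + 0.5) - cy
    ang = np.arctan2(y, x)
    rad = np.hypot(x, y)
    r = np.full_like(ang, r0)
    for k in range(2, 5):
        amp = rng.uniform(0.05, 0.22) * r0
        ph = rng.uniform(0, 2 * math.pi)
        r = r + amp * np.cos(k * ang + ph)
    return rad / np.maximum(r, 1e-6)


def _stamp(img, mask_q, color, strength, soft=0.35):
    """Blend `color` into img where the quadratic-form mask < 1 + soft.

    Returns the visibly-changed mask (blend weight above a small cutoff), so
    tight bounding boxes cover the whole drawn extent including soft edges.
    """
    w = np.clip((1.0 + soft - mask_q) / soft, 0.0, 1.0) * strength
    img[:] = img * (1 - w[..., None]) + color[None, None] * w[..., None]
    return w > 0.02


def _tight_bbox(drawn: np.ndarray):
    ys, xs = np.nonzero(drawn)
    return xs.min(), ys.min(), xs.max() + 1, ys.max() + 1


def place_targets(bg: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> LabeledImage:
    """Draw Poisson-count burrows, dung and unlabeled distractors onto a copy
    of ``bg``; returns the image with tight normalized labels."""
    size = cfg.image_size
    img = bg.astype(np.float32).copy()
    labels = []
    centers, radii = [], []

    def far_enough(cx, cy, r):
        return all(math.hypot(cx - px, cy - py) >= max(r, pr)
                   for (px, py), pr in zip(centers, radii))

    def sample_center(r, tries=25):
        margin = 2.0 * r + 2
        for _ in range(tries):
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            if far_enough(cx, cy, 3.0 * r):
                return cx, cy
        return None

    n_burrow = rng.poisson(cfg.burrow_rate)
    n_dung = rng.poisson(cfg.dung_rate)
    n_distr = rng.poisson(cfg.distractor_rate)

    for _ in range(n_burrow):
        a = rng.uniform(*cfg.burrow_radius)
        b = a * rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, math.pi)
        c = rng.uniform(*cfg.contrast)
        pos = sample_center(a)
        if pos is None:
            continue
        cx, cy = pos
        q = _ellipse_mask(size, cx, cy, a, b, theta)
        # lighter excavated-soil rim first, dark entrance on top
        rim_q = _ellipse_mask(size, cx, cy, 1.45 * a, 1.45 * b, theta)
        rim = _stamp(img, rim_q, _RIM_SOIL, 0.45 * c)
        hole = _stamp(img, q, _BURROW_DARK, c)
        x1, y1, x2, y2 = _tight_bbox(rim | hole)
        labels.append((0, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                       (x2 - x1) / size, (y2 - y1) / size))
        centers.append((cx, cy))
        radii.append(1.45 * a)

    for _ in range(n_dung):
        r0 = rng.uniform(*cfg.dung_radius)
        c = rng.uniform(*cfg.contrast)
        pos = sample_center(r0 * 1.3)
        if pos is None:
            continue
        cx, cy = pos
        q = _blob_mask(size, cx, cy, r0, rng)
        shade = _DUNG_BROWN + rng.normal(0, 6, 3).astype(np.float32)
        drawn = _stamp(img, q, shade, c)
        x1, y1, x2, y2 = _tight_bbox(drawn)
        labels.append((1, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                       (x2 - x1) / size, (y2 - y1) / size))
        centers.append((cx, cy))
        radii.append(1.3 * r0)

    for _ in range(n_distr):
        r0 = rng.uniform(3.0, 9.0)
        pos = sample_center(r0)
        if pos is None:
            continue
        cx, cy = pos
        if rng.random() < 0.5:   # stone
            q = _ellipse_mask(size, cx, cy, r0, r0 * rng.uniform(0.6, 1.0),
                              rng.uniform(0, math.pi))
            _stamp(img, q, _STONE_GRAY, rng.uniform(0.3, 0.6))
        else:                    # shadow
            q = _blob_mask(size, cx, cy, r0 * 1.4, rng)
            _stamp(img, q, _BURROW_DARK * 1.6, rng.uniform(0.2, 0.4), soft=1.2)
        centers.append((cx, cy))
        radii.append(r0)

    return LabeledImage(np.clip(img, 0, 255).astype(np.uint8), labels)


def generate_scene(cfg: SceneConfig, index: int = 0) -> LabeledImage:
    """One deterministic scene; ``index`` streams independent images."""
    rng = np.random.default_rng((cfg.seed, index))
    bg = generate_background(cfg, rng)
    return place_targets(bg, cfg, rng)


# ---------------------------------------------------------------------------
# dataset rendering
# ---------------------------------------------------------------------------

def format_label_line(label) -> str:
    cid, cx, cy, w, h = label
    return f"{int(cid)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"


def split_counts(n: int, split=(0.8, 0.1, 0.1)):
    """Floor-rounded split sizes with the remainder assigned to train."""
    if abs(sum(split) - 1.0) > 1e-6:
        raise ValueError("split ratios must sum to 1")
    n_val = int(n * split[1])
    n_test = int(n * split[2])
    return n - n_val - n_test, n_val, n_test


def render_dataset(cfg: SceneConfig, n_images: int, out_dir,
                   split=(0.8, 0.1, 0.1)) -> Path:
    """Write a YOLO-layout dataset + YAML manifest; returns the manifest path."""
    import yaml

    out = Path(out_dir)
    n_train, n_val, n_test = split_counts(n_images, split)
    sizes = {"train": n_train, "val": n_val, "test": n_test}
    idx = 0
    for part, count in sizes.items():
        (out / "images" / part).mkdir(parents=True, exist_ok=True)
        (out / "labels" / part).mkdir(parents=True, exist_ok=True)
        for _ in range(count):
            scene = generate_scene(cfg, idx)
            Image.fromarray(scene.pixels).save(out / "images" / part / f"{idx:06d}.png")
            text = "\n".join(format_label_line(lb) for lb in scene.labels)
            (out / "labels" / part / f"{idx:06d}.txt").write_text(
                text + ("\n" if text else ""))
            idx += 1
    manifest = {
        "path": str(out.resolve()),
        "train": "images/train",
        "val": "images/val",
        "test": "images/test",
        "nc": 2,
        "names": dict(CLASS_NAMES),
        "image_size": cfg.image_size,
    }
    mpath = out / "dataset.yaml"
    mpath.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return mpath
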