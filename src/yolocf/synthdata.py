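"""Procedural generator of annotated orchard-style fruit scenes.

Real fruit-image collections mix conditions that make detection hard:
fruit clusters, leaf/branch occlusion, overlapping and densely packed
targets, strong illumination changes (backlight, side light, low light),
backgrounds that resemble the fruit, and wide size variation.  This module
renders small RGB scenes that exhibit those conditions with *exact* box
labels, so every downstream stage (assignment, loss, training, evaluation,
counting) can be exercised without a field dataset.

Fruits are shaded ellipse/capsule primitives with per-class colour, shape
and texture; occluders are foliage-coloured ellipses and branch strips
drawn over them.  Labels annotate the full (amodal) fruit extent; a
visible-area floor guarantees no target is occluded into unlearnability.

Everything is driven by one integer seed through a hierarchical stream
(dataset -> scene -> object), so any subset regenerates bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

CLASS_NAMES = ("bitter-melon", "cucumber", "cherry", "jujube",
               "melon-boyang", "muskmelon", "strawberry")
# per-class share of images in the emulated collection
CLASS_PROPORTIONS = np.array([665, 664, 474, 1026, 736, 404, 981], float)
CLASS_PROPORTIONS /= CLASS_PROPORTIONS.sum()

# colour (RGB), shape, texture amplitude, size range (fraction of image)
CLASS_STYLES = (
    {"color": (170, 200, 90), "shape": "elongated", "texture": 0.25,
     "size": (0.05, 0.11)},   # bitter-melon: pale warty green
    {"color": (60, 120, 45), "shape": "elongated", "texture": 0.10,
     "size": (0.05, 0.12)},   # cucumber: dark green
    {"color": (200, 30, 45), "shape": "round", "texture": 0.05,
     "size": (0.025, 0.055)},  # cherry: small glossy red
    {"color": (150, 60, 40), "shape": "round", "texture": 0.08,
     "size": (0.03, 0.06)},   # jujube: red-brown
    {"color": (225, 225, 160), "shape": "round", "texture": 0.06,
     "size": (0.07, 0.16)},   # melon-boyang: pale yellow
    {"color": (195, 165, 110), "shape": "round", "texture": 0.30,
     "size": (0.08, 0.17)},   # muskmelon: netted tan
    {"color": (220, 50, 60), "shape": "round", "texture": 0.18,
     "size": (0.03, 0.07)},   # strawberry: seeded red
)

ILLUMINATIONS = ("high_light", "low_light", "backlight", "side_light")
BACKGROUNDS = ("earth", "foliage_similar", "sky")

CONDITION_TYPES = ("fruit_cluster", "leaf_occlusion", "overlap", "backlight",
                   "dense_targets", "branch_occlusion", "earth_background",
                   "similar_background", "sky_background", "size_variation")


@dataclass
class SceneSpec:
    n_classes: int = 7
    image_size: int = 640
    objects_per_image: tuple = (1, 8)
    occluder_density: float = 0.5   # expected occluders per fruit
    illumination: str = "mixed"     # one of ILLUMINATIONS or "mixed"
    cluster_probability: float = 0.3
    background: str = "mixed"       # one of BACKGROUNDS or "mixed"
    visible_floor: float = 0.25
    proportional_classes: bool = False
    size_scale: float = 1.0  # 1.0 = distant-canopy framing; >1 = close range
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_classes <= len(CLASS_STYLES):
            raise ValueError("n_classes must be in 1..7")
        if self.illumination not in ILLUMINATIONS + ("mixed",):
            raise ValueError(f"unknown illumination {self.illumination!r}")
        if self.background not in BACKGROUNDS + ("mixed",):
            raise ValueError(f"unknown background {self.background!r}")


@dataclass
class SceneData:
    image: np.ndarray          # (H, W, 3) uint8
    labels: np.ndarray         # (n, 5): class cx cy w h, normalized
    masks: list                # per-object boolean (H, W) pre-occlusion
    conditions: set = field(default_factory=set)
    visible_fractions: list = field(default_factory=list)


def _background(kind: str, size: int, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / size
    noise = rng.normal(0, 1, (size, size))
    # cheap smoothing: two box passes
    for ax in (0, 1):
        noise = (np.roll(noise, 1, ax) + noise + np.roll(noise, -1, ax)) / 3
    noise -= noise.min()
    noise /= max(np.ptp(noise), 1e-9)
    img = np.zeros((size, size, 3))
    if kind == "earth":
        base = np.array([120, 90, 60])
        img[:] = base * (0.7 + 0.5 * noise[..., None])
    elif kind == "foliage_similar":
        base = np.array([70, 110, 50])
        img[:] = base * (0.6 + 0.7 * noise[..., None])
        for _ in range(int(size / 20)):
            cx, cy = rng.uniform(0, size, 2)
            r = rng.uniform(size / 30, size / 10)
            m = (xx * size - cx) ** 2 + (yy * size - cy) ** 2 < r**2
            img[m] = np.array([55, 95, 40]) * rng.uniform(0.7, 1.3)
    else:  # sky
        img[:] = (np.array([150, 185, 235]) * (1 - 0.35 * yy[..., None])
                  + 18 * noise[..., None])
    return img.clip(0, 255)


def _ellipse_mask(size, cx, cy, rx, ry, angle):
    yy, xx = np.mgrid[0:size, 0:size] + 0.5
    dx, dy = xx - cx, yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / rx
    v = (-dx * sa + dy * ca) / ry
    return u * u + v * v <= 1.0, (u, v)


def _fruit_geometry(size, cls, cx, cy, r, angle, rng):
    style = CLASS_STYLES[cls]
    if style["shape"] == "elongated":
        rx, ry = r * rng.uniform(1.6, 2.4), r * rng.uniform(0.55, 0.8)
    else:
        rx, ry = r * rng.uniform(0.9, 1.15), r * rng.uniform(0.85, 1.05)
    mask, (u, v) = _ellipse_mask(size, cx, cy, rx, ry, angle)
    if not mask.any():
        return None
    # analytic amodal bbox of the rotated ellipse
    ca, sa = np.cos(angle), np.sin(angle)
    hx = np.sqrt((rx * ca) ** 2 + (ry * sa) ** 2)
    hy = np.sqrt((rx * sa) ** 2 + (ry * ca) ** 2)
    box = np.array([cx / size, cy / size, 2 * hx / size, 2 * hy / size])
    return mask, (u, v), box


def _render_fruit(img, mask, uv, cls, rng):
    style = CLASS_STYLES[cls]
    u, v = uv
    color = np.array(style["color"], float) * rng.uniform(0.85, 1.15)
    rad2 = (u * u + v * v)[mask]
    shade = 1.0 - 0.45 * rad2                       # spherical shading
    tex = style["texture"] * np.sin(
        u[mask] * rng.uniform(8, 16) + v[mask] * rng.uniform(8, 16))
    px = color[None, :] * (shade + tex)[:, None]
    # specular highlight
    hl = np.exp(-((u[mask] + 0.35) ** 2 + (v[mask] + 0.35) ** 2) / 0.08)
    px += 80 * hl[:, None]
    img[mask] = px.clip(0, 255)


def _clip_box(box):
    cx, cy, w, h = box
    x1, y1 = max(cx - w / 2, 0.0), max(cy - h / 2, 0.0)
    x2, y2 = min(cx + w / 2, 1.0), min(cy + h / 2, 1.0)
    if x2 - x1 <= 1e-4 or y2 - y1 <= 1e-4:
        return None
    return np.array([(x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1])


def _occluder(img, size, kind, cx, cy, r, angle, rng):
    if kind == "leaf":
        mask, (u, v) = _ellipse_mask(size, cx, cy, r * 1.4, r * 0.8, angle)
        color = np.array([65, 105, 45]) * rng.uniform(0.75, 1.25)
        if mask.any():
            vein = 0.15 * np.cos(v[mask] * 9)
            img[mask] = (color[None, :] * (0.85 + vein)[:, None]).clip(0, 255)
    else:  # branch: long thin strip
        mask, _ = _ellipse_mask(size, cx, cy, r * 3.0, r * 0.18, angle)
        if mask.any():
            img[mask] = np.array([95, 70, 45]) * rng.uniform(0.8, 1.2)
    return mask


def _apply_illumination(img, kind, size):
    yy, xx = np.mgrid[0:size, 0:size] / size
    if kind == "high_light":
        img = img * 1.25 + 18
    elif kind == "low_light":
        img = img * 0.55
    elif kind == "backlight":
        img = img * (0.45 + 0.15 * yy[..., None]) + 90 * np.exp(
            -((yy - 0.05) ** 2) / 0.02)[..., None]
    else:  # side_light
        img = img * (0.5 + 0.8 * xx[..., None])
    return img.clip(0, 255)


def generate_scene(spec: SceneSpec, rng=None, *, full: bool = False):
    """Render one scene.  Returns ``(image, labels)`` or, with ``full=True``,
    a :class:`SceneData` including instance masks and condition tags."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    size = spec.image_size
    bg = (spec.background if spec.background != "mixed"
          else BACKGROUNDS[rng.integers(len(BACKGROUNDS))])
    illum = (spec.illumination if spec.illumination != "mixed"
             else ILLUMINATIONS[rng.integers(len(ILLUMINATIONS))])
    img = _background(bg, size, rng)
    conditions = {f"{'similar' if bg == 'foliage_similar' else bg}_background"}
    if illum == "backlight":
        conditions.add("backlight")

    lo, hi = spec.objects_per_image
    n_obj = int(rng.integers(lo, hi + 1))
    clustered = n_obj >= 2 and rng.random() < spec.cluster_probability
    if clustered:
        conditions.add("fruit_cluster")
    if spec.proportional_classes:
        scene_cls = int(rng.choice(spec.n_classes,
                                   p=CLASS_PROPORTIONS[:spec.n_classes]
                                   / CLASS_PROPORTIONS[:spec.n_classes].sum()))
    else:
        scene_cls = int(rng.integers(spec.n_classes))

    masks, labels, sizes = [], [], []
    visible = []  # unoccluded pixel count per fruit
    cluster_c = rng.uniform(0.25, 0.75, 2) * size
    placed = 0
    for _ in range(n_obj * 4):  # bounded retries
        if placed >= n_obj:
            break
        s_lo, s_hi = CLASS_STYLES[scene_cls]["size"]
        r = rng.uniform(s_lo, s_hi) * size * spec.size_scale
        if clustered:
            cx, cy = cluster_c + rng.normal(0, 1.6 * r, 2)
        else:
            cx, cy = rng.uniform(0.05, 0.95, 2) * size
        if not (-r < cx < size + r and -r < cy < size + r):
            continue
        geo = _fruit_geometry(size, scene_cls, cx, cy, r,
                              rng.uniform(0, np.pi), rng)
        if geo is None:
            continue
        mask, uv, box = geo
        box = _clip_box(box)
        if box is None:
            continue
        # keep earlier fruits above the visible-area floor
        if any(visible[i] - (masks[i] & mask).sum()
               < spec.visible_floor * masks[i].sum()
               for i in range(placed)):
            continue
        _render_fruit(img, mask, uv, scene_cls, rng)
        for i in range(placed):
            visible[i] -= (masks[i] & mask).sum()
        masks.append(mask)
        visible.append(int(mask.sum()))
        labels.append(np.array([scene_cls, *box]))
        sizes.append(r)
        placed += 1

    if placed >= 2:
        boxes = np.array([lab[1:] for lab in labels])
        x1y1 = boxes[:, :2] - boxes[:, 2:] / 2
        x2y2 = boxes[:, :2] + boxes[:, 2:] / 2
        tl = np.maximum(x1y1[:, None], x1y1[None])
        br = np.minimum(x2y2[:, None], x2y2[None])
        inter = np.clip(br - tl, 0, None).prod(-1)
        np.fill_diagonal(inter, 0)
        if (inter > 0.1 * boxes[:, 2:].prod(-1)).any():
            conditions.add("overlap")
    if placed >= 8:
        conditions.add("dense_targets")
    if sizes and max(sizes) > 1.8 * min(sizes):
        conditions.add("size_variation")

    # occluders, respecting the visible-area floor
    n_occ = rng.poisson(spec.occluder_density * max(placed, 1))
    for _ in range(n_occ):
        kind = "leaf" if rng.random() < 0.7 else "branch"
        if masks and rng.random() < 0.8:  # aim at a fruit edge
            t = rng.integers(len(masks))
            ys, xs = np.nonzero(masks[t])
            j = rng.integers(len(xs))
            cx, cy = float(xs[j]), float(ys[j])
        else:
            cx, cy = rng.uniform(0, size, 2)
        r = rng.uniform(0.03, 0.08) * size
        omask, _ = _ellipse_mask(size, cx, cy, r * (3.0 if kind == "branch"
                                                    else 1.4),
                                 r * (0.18 if kind == "branch" else 0.8),
                                 rng.uniform(0, np.pi))
        ok = True
        for i, m in enumerate(masks):
            if visible[i] == 0:
                continue
            remain = visible[i] - (m & omask).sum()
            if remain < spec.visible_floor * m.sum():
                ok = False
                break
        if not ok:
            continue
        _occluder(img, size, kind, cx, cy, r, rng.uniform(0, np.pi), rng)
        for i, m in enumerate(masks):
            visible[i] -= (m & omask).sum()
        conditions.add("leaf_occlusion" if kind == "leaf"
                       else "branch_occlusion")

    img = _apply_illumination(img, illum, size)
    img += rng.normal(0, 2.5, img.shape)  # sensor noise
    image = img.clip(0, 255).astype(np.uint8)
    label_arr = (np.array(labels) if labels
                 else np.empty((0, 5)))
    if full:
        fracs = [v / m.sum() for v, m in zip(visible, masks)]
        return SceneData(image, label_arr, masks, conditions, fracs)
    return image, label_arr


def difficulty_presets() -> dict:
    """Named generation regimes.

    ``easy``        — sparse, unoccluded, uniform bright light (smoke tests).
    ``cfruit_like`` — the mixed-conditions regime emulating the field
                      collection's stated difficulty factors.
    ``hard``        — heavy occlusion and dense clusters.
    """
    return {
        "easy": SceneSpec(objects_per_image=(1, 4), occluder_density=0.0,
                          illumination="high_light", cluster_probability=0.0,
                          background="earth", size_scale=2.0),
        "cfruit_like": SceneSpec(objects_per_image=(1, 12),
                                 occluder_density=0.8,
                                 illumination="mixed",
                                 cluster_probability=0.35,
                                 background="mixed",
                                 proportional_classes=True),
        "hard": SceneSpec(objects_per_image=(6, 16), occluder_density=1.5,
                          illumination="mixed", cluster_probability=0.7,
                          background="mixed"),
    }


def write_labels(path, labels):
    with open(path, "w") as f:
        for row in labels:
            f.write(f"{int(row[0])} " + " ".join(f"{v:.6f}" for v in row[1:])
                    + "\n")


def read_labels(path) -> np.ndarray:
    rows = []
    with open(path) as f:
        for line in f:
            parts = line.split()
            if parts:
                rows.append([float(p) for p in parts])
    return np.array(rows).reshape(-1, 5) if rows else np.empty((0, 5))


def write_dataset(root, spec: SceneSpec, n_train: int, n_val: int,
                  split_seed: int | None = None,
                  overwrite: bool = False) -> Path:
    """Materialise a dataset in YOLO layout and return the config path.

    ``images/{train,val}/*.png`` + ``labels/{train,val}/*.txt`` + a YAML
    config listing the class names.
    """
    from PIL import Image

    root = Path(root)
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"{root} is not empty (pass overwrite=True)")
    seed = spec.seed if split_seed is None else split_seed
    ss = np.random.SeedSequence(seed)
    for sub in ("images/train", "images/val", "labels/train", "labels/val"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    children = ss.spawn(n_train + n_val)
    for i, child in enumerate(children):
        split = "train" if i < n_train else "val"
        idx = i if i < n_train else i - n_train
        rng = np.random.default_rng(child)
        image, labels = generate_scene(spec, rng)
        Image.fromarray(image).save(root / f"images/{split}/{idx:05d}.png")
        write_labels(root / f"labels/{split}/{idx:05d}.txt", labels)
    cfg = {"path": ".", "train": "images/train", "val": "images/val",
           "nc": spec.n_classes,
           "names": list(CLASS_NAMES[:spec.n_classes])}
    cfg_path = root / "data.yaml"
    with open(cfg_path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
    with open(root / "genspec.yaml", "w") as f:
        yaml.safe_dump({"seed": seed, "n_train": n_train, "n_val": n_val,
                        **dataclasses.asdict(spec)}, f, sort_keys=False)
    return cfg_path
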