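"""Training loop, augmentation and dataset plumbing.

Defaults mirror the experimental regime the detector was designed under:
640-pixel inputs, batch 16, 200 epochs, SGD momentum 0.937, HSV gains
(0.015, 0.7, 0.4), translate 0.1, scale 0.5, mosaic probability 1.0.
Anything unstated there (learning rate, schedule, loss weights) uses the
YOLOv5-platform defaults.  Scaled-down smoke regimes (160 px, tens of
epochs) are plain configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .loss import detection_loss
from .metrics import counts_from_detections, evaluate_detections
from .model import Detector, autoanchor, save_checkpoint
from .nn.autograd import no_grad
from .nn.optim import SGD, split_decay_groups, warmup_cosine_lr
from .postprocess import EVAL_CONF, decode, letterbox, nms
from .synthdata import read_labels


@dataclass
class HyperParams:
    img_size: int = 640
    batch: int = 16
    epochs: int = 200
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    warmup_epochs: float = 3.0
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    translate: float = 0.1
    scale: float = 0.5
    fliplr: float = 0.5
    mosaic: float = 1.0
    use_autoanchor: bool = True
    conf_eval: float = EVAL_CONF
    iou_nms: float = 0.45
    seed: int = 0

    def __post_init__(self):
        for name in ("hsv_h", "hsv_s", "hsv_v", "translate", "mosaic",
                     "fliplr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(asdict(self), sort_keys=False)
        if path:
            with open(path, "w") as f:
                f.write(s)
        return s


class YoloDataset:
    """YOLO-layout image/label pairs, cached in memory, letterboxed."""

    def __init__(self, data_cfg, split: str = "train", img_size: int = 640):
        from PIL import Image

        cfg = data_cfg
        base = Path(".")
        if not isinstance(cfg, dict):
            base = Path(cfg).parent
            with open(cfg) as f:
                cfg = yaml.safe_load(f)
        root = Path(cfg["path"])
        if not root.is_absolute():
            root = (base / root).resolve()
        img_dir = root / cfg[split]
        self.num_classes = int(cfg["nc"])
        self.names = list(cfg["names"])
        self.img_size = img_size
        self.images, self.labels = [], []
        for p in sorted(img_dir.glob("*")):
            if p.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            img = np.asarray(Image.open(p).convert("RGB"))
            lab = read_labels(root / "labels" / split / (p.stem + ".txt"))
            img, lab = self._letterbox_pair(img, lab)
            self.images.append(img)
            self.labels.append(lab)
        if not self.images:
            raise FileNotFoundError(f"no images under {img_dir}")

    def _letterbox_pair(self, img, lab):
        h, w = img.shape[:2]
        out, r, (dw, dh) = letterbox(img, self.img_size)
        if len(lab):
            lab = lab.copy()
            S = self.img_size
            lab[:, 1] = (lab[:, 1] * w * r + dw) / S
            lab[:, 2] = (lab[:, 2] * h * r + dh) / S
            lab[:, 3] = lab[:, 3] * w * r / S
            lab[:, 4] = lab[:, 4] * h * r / S
        return out, lab

    def __len__(self):
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i], self.labels[i]


# -- augmentation -----------------------------------------------------------

def _paste(canvas, img, x1, y1, x2, y2):
    """Nearest-resample `img` into canvas[y1:y2, x1:x2]."""
    th, tw = y2 - y1, x2 - x1
    if th <= 0 or tw <= 0:
        return
    h, w = img.shape[:2]
    ys = (np.arange(th) * h / th).astype(int).clip(0, h - 1)
    xs = (np.arange(tw) * w / tw).astype(int).clip(0, w - 1)
    canvas[y1:y2, x1:x2] = img[ys][:, xs]


def mosaic_augment(samples, rng, out_size: int | None = None,
                   center_jitter: float = 0.25, min_box_px: float = 2.0):
    """2x2 collage of four (image, labels) samples around a jittered center.

    Labels are remapped affinely per quadrant and clipped; boxes collapsing
    below ``min_box_px`` are dropped.
    """
    if len(samples) != 4:
        raise ValueError("mosaic requires exactly four samples")
    S = out_size or samples[0][0].shape[0]
    cx = int(S * (0.5 + center_jitter * rng.uniform(-1, 1)))
    cy = int(S * (0.5 + center_jitter * rng.uniform(-1, 1)))
    cx, cy = np.clip([cx, cy], S // 4, 3 * S // 4)
    canvas = np.full((S, S, 3), 114, dtype=np.uint8)
    rects = [(0, 0, cx, cy), (cx, 0, S, cy), (0, cy, cx, S), (cx, cy, S, S)]
    out_labels = []
    for (img, lab), (x1, y1, x2, y2) in zip(samples, rects):
        _paste(canvas, img, x1, y1, x2, y2)
        if not len(lab):
            continue
        rw, rh = x2 - x1, y2 - y1
        l2 = lab.copy()
        l2[:, 1] = (lab[:, 1] * rw + x1) / S
        l2[:, 2] = (lab[:, 2] * rh + y1) / S
        l2[:, 3] = lab[:, 3] * rw / S
        l2[:, 4] = lab[:, 4] * rh / S
        out_labels.append(l2)
    labels = (np.concatenate(out_labels) if out_labels
              else np.empty((0, 5)))
    labels = _clip_labels(labels, S, min_box_px)
    return canvas, labels


def _clip_labels(labels, size_px, min_box_px=2.0):
    if not len(labels):
        return labels
    x1 = np.clip(labels[:, 1] - labels[:, 3] / 2, 0, 1)
    y1 = np.clip(labels[:, 2] - labels[:, 4] / 2, 0, 1)
    x2 = np.clip(labels[:, 1] + labels[:, 3] / 2, 0, 1)
    y2 = np.clip(labels[:, 2] + labels[:, 4] / 2, 0, 1)
    out = np.stack([labels[:, 0], (x1 + x2) / 2, (y1 + y2) / 2,
                    x2 - x1, y2 - y1], axis=1)
    keep = (out[:, 3] * size_px >= min_box_px) & (out[:, 4] * size_px >= min_box_px)
    return out[keep]


def hsv_augment(image: np.ndarray, gains, rng) -> np.ndarray:
    """Random hue/saturation/value jitter within the given fractional gains."""
    from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

    gh, gs, gv = gains
    if gh == gs == gv == 0:
        return image.copy()
    u = rng.uniform(-1, 1, 3)
    hsv = rgb_to_hsv(image.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + gh * u[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * (1 + gs * u[1]), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * (1 + gv * u[2]), 0, 1)
    return (hsv_to_rgb(hsv) * 255.0).round().clip(0, 255).astype(np.uint8)


def affine_augment(image, labels, rng, translate=0.1, scale=0.5):
    """Random isotropic scale + translation (nearest resample)."""
    S = image.shape[0]
    f = rng.uniform(1 - scale, 1 + scale)
    tx = rng.uniform(-translate, translate) * S
    ty = rng.uniform(-translate, translate) * S
    ys = ((np.arange(S) - S / 2 - ty) / f + S / 2).astype(int)
    xs = ((np.arange(S) - S / 2 - tx) / f + S / 2).astype(int)
    valid_y = (ys >= 0) & (ys < S)
    valid_x = (xs >= 0) & (xs < S)
    out = np.full_like(image, 114)
    out[np.ix_(valid_y, valid_x)] = image[ys[valid_y]][:, xs[valid_x]]
    if len(labels):
        labels = labels.copy()
        labels[:, 1] = ((labels[:, 1] * S - S / 2) * f + S / 2 + tx) / S
        labels[:, 2] = ((labels[:, 2] * S - S / 2) * f + S / 2 + ty) / S
        labels[:, 3] *= f
        labels[:, 4] *= f
        labels = _clip_labels(labels, S)
    return out, labels


def _flip_lr(image, labels):
    image = image[:, ::-1].copy()
    if len(labels):
        labels = labels.copy()
        labels[:, 1] = 1.0 - labels[:, 1]
    return image, labels


# -- training ---------------------------------------------------------------

def _make_batch(dataset, idxs, hyp, rng, train=True):
    imgs, labs = [], []
    for bi, i in enumerate(idxs):
        if train and rng.random() < hyp.mosaic:
            others = rng.integers(0, len(dataset), 3)
            samples = [dataset[i]] + [dataset[j] for j in others]
            img, lab = mosaic_augment(samples, rng)
        else:
            img, lab = dataset[i]
            lab = lab.copy()
        if train:
            img, lab = affine_augment(img, lab, rng, hyp.translate, hyp.scale)
            img = hsv_augment(img, (hyp.hsv_h, hyp.hsv_s, hyp.hsv_v), rng)
            if rng.random() < hyp.fliplr:
                img, lab = _flip_lr(img, lab)
        imgs.append(img)
        if len(lab):
            labs.append(np.concatenate(
                [np.full((len(lab), 1), bi), lab], axis=1))
    x = np.stack(imgs).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
    labels = np.concatenate(labs) if labs else np.empty((0, 6))
    return x, labels


def _val_pass(model, dataset, hyp):
    """Validation losses plus decoded detections for mAP."""
    anchors = model.config.anchors
    nc = model.config.num_classes
    model.eval()
    tot = np.zeros(3)
    n_batches = 0
    preds = []
    rng = np.random.default_rng(0)
    for start in range(0, len(dataset), hyp.batch):
        idxs = range(start, min(start + hyp.batch, len(dataset)))
        x, labels = _make_batch(dataset, list(idxs), hyp, rng, train=False)
        with no_grad():
            raws = model(x)
        lb = detection_loss(raws, labels, anchors, nc)
        tot += (lb.box_loss, lb.obj_loss, lb.cls_loss)
        n_batches += 1
        dets = decode(raws, anchors, hyp.conf_eval, model.config.img_size)
        preds.extend(nms(d, hyp.iou_nms) for d in dets)
    metrics = evaluate_detections(preds, dataset.labels, nc)
    model.train()
    return tot / n_batches, metrics, preds


def train(model: Detector, data_cfg, hyp: HyperParams,
          out_dir=None, log=print) -> list:
    """Train the detector; returns per-epoch history records.

    Each record carries train/val box-obj-cls losses, P, R and mAP@0.5.
    The best-mAP checkpoint (and the last) are written under ``out_dir``.
    """
    rng = np.random.default_rng(hyp.seed)
    train_ds = YoloDataset(data_cfg, "train", hyp.img_size)
    val_ds = YoloDataset(data_cfg, "val", hyp.img_size)
    if train_ds.num_classes != model.config.num_classes:
        raise ValueError("dataset / model class-count mismatch")
    if hyp.use_autoanchor:
        all_labels = np.concatenate([l for l in train_ds.labels if len(l)])
        model.config.anchors = autoanchor(all_labels, 9, hyp.img_size,
                                          seed=hyp.seed)
    anchors = model.config.anchors
    nc = model.config.num_classes
    opt = SGD(split_decay_groups(model), lr=hyp.lr0, momentum=hyp.momentum,
              weight_decay=hyp.weight_decay)
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        hyp.to_yaml(out_dir / "hyp.yaml")
    history, best_map = [], -1.0
    n = len(train_ds)
    for epoch in range(hyp.epochs):
        t0 = time.time()
        model.train()
        opt.lr = warmup_cosine_lr(epoch, hyp.epochs, hyp.lr0, hyp.lrf,
                                  hyp.warmup_epochs)
        perm = rng.permutation(n)
        ep_loss = np.zeros(3)
        nb = 0
        for start in range(0, n, hyp.batch):
            idxs = perm[start:start + hyp.batch]
            x, labels = _make_batch(train_ds, idxs, hyp, rng, train=True)
            raws = model(x)
            lb = detection_loss(raws, labels, anchors, nc)
            opt.zero_grad()
            lb.total.backward()
            opt.step()
            ep_loss += (lb.box_loss, lb.obj_loss, lb.cls_loss)
            nb += 1
        val_loss, metrics, _ = _val_pass(model, val_ds, hyp)
        rec = {
            "epoch": epoch, "lr": opt.lr,
            "train_box": ep_loss[0] / nb, "train_obj": ep_loss[1] / nb,
            "train_cls": ep_loss[2] / nb,
            "val_box": float(val_loss[0]), "val_obj": float(val_loss[1]),
            "val_cls": float(val_loss[2]),
            "precision": float(metrics.precision.mean()),
            "recall": float(metrics.recall.mean()),
            "map50": metrics.map50,
            "seconds": round(time.time() - t0, 2),
        }
        history.append(rec)
        if log:
            log(f"epoch {epoch:3d}  box {rec['val_box']:.3f}  "
                f"obj {rec['val_obj']:.3f}  cls {rec['val_cls']:.3f}  "
                f"mAP50 {rec['map50']:.3f}  ({rec['seconds']}s)")
        if out_dir:
            with open(out_dir / "log.jsonl", "a") as f:
                f.write(json.dumps(rec) + "\n")
            save_checkpoint(model, out_dir / "last.npz")
            if metrics.map50 > best_map:
                best_map = metrics.map50
                save_checkpoint(model, out_dir / "best.npz")
    return history


def evaluate_model(model: Detector, data_cfg, split="val",
                   conf=EVAL_CONF, iou_nms=0.45, img_size=None):
    """Decode + NMS + dataset metrics for a trained model."""
    img_size = img_size or model.config.img_size
    ds = YoloDataset(data_cfg, split, img_size)
    hyp = HyperParams(img_size=img_size, batch=8, conf_eval=conf,
                      iou_nms=iou_nms)
    _, metrics, preds = _val_pass(model, ds, hyp)
    return metrics, preds, ds


def count_objects(model: Detector, data_cfg, split="val", conf=0.25,
                  iou_nms=0.45, per_class=False):
    """Per-image predicted vs. true counts and their agreement report."""
    from .metrics import count_analysis

    metrics, preds, ds = evaluate_model(model, data_cfg, split, conf, iou_nms)
    pred_counts = counts_from_detections(
        preds, per_class, model.config.num_classes)
    if per_class:
        true_counts = counts_from_detections(
            [[_DetStub(int(l[0])) for l in labs] for labs in ds.labels],
            True, model.config.num_classes)
        return count_analysis(true_counts.ravel(), pred_counts.ravel())
    true_counts = np.array([len(l) for l in ds.labels])
    return count_analysis(true_counts, pred_counts)


class _DetStub:
    def __init__(self, class_id):
        self.class_id = class_id
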