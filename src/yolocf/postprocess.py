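"""Decoding raw head outputs into detections, NMS, letterboxing, timing.

Decode arithmetic is the anchor-based convention: per anchor and cell,

    xy = (2*sigmoid(t_xy) - 0.5 + grid) * stride
    wh = (2*sigmoid(t_wh))^2 * anchor
    score = sigmoid(t_obj) * max_c sigmoid(t_cls_c)

``encode_targets`` is the exact inverse and exists so the decode transform
can be validated by round-trip.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass

import numpy as np

from .loss import BoxXYWHN
from .model import AnchorSet
from .nn.autograd import Tensor

DEFAULT_CONF = 0.25
DEFAULT_IOU = 0.45
EVAL_CONF = 0.001  # confidence floor used when sweeping PR curves


@dataclass(frozen=True)
class Detection:
    box: BoxXYWHN      # normalized to the decoded image size
    class_id: int
    score: float

    def xyxy(self, width: float = 1.0, height: float = 1.0):
        x1, y1, x2, y2 = self.box.to_corners()
        return (x1 * width, y1 * height, x2 * width, y2 * height)


@dataclass(frozen=True)
class TimingReport:
    t_pre: float    # ms
    t_infer: float  # ms
    t_post: float   # ms

    @property
    def fps(self) -> float:
        return 1000.0 / (self.t_pre + self.t_infer + self.t_post)


def _sigmoid(x):
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(raws, anchors: AnchorSet, conf_threshold: float = DEFAULT_CONF,
           img_size: int | None = None, max_det: int = 300) -> list:
    """Decode per-scale raw maps into per-image lists of :class:`Detection`.

    ``raws``: list of (N, 3*(5+nc), H, W) arrays/Tensors, one per stride.
    Returns a list of N lists of detections (normalized boxes), each capped
    at the ``max_det`` highest-scoring candidates.
    """
    raws = [r.data if isinstance(r, Tensor) else np.asarray(r) for r in raws]
    if len(raws) != len(anchors.strides):
        raise ValueError("one raw map per anchor scale required")
    N = raws[0].shape[0]
    no = raws[0].shape[1] // 3
    size = img_size or raws[0].shape[2] * anchors.strides[0]
    rows = [[] for _ in range(N)]  # (score, cx, cy, w, h, cls) arrays
    anc = anchors.as_array()
    for raw, stride, a in zip(raws, anchors.strides, anc):
        _, ch, H, W = raw.shape
        if ch != 3 * no:
            raise ValueError("channel count inconsistent across scales")
        p = _sigmoid(raw.reshape(N, 3, no, H, W).transpose(0, 1, 3, 4, 2))
        gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        xy = (p[..., 0:2] * 2.0 - 0.5
              + np.stack([gx, gy], axis=-1)) * stride
        wh = (p[..., 2:4] * 2.0) ** 2 * a[None, :, None, None, :]
        cls_p = p[..., 5:]
        best_c = cls_p.argmax(axis=-1)
        score = p[..., 4] * np.take_along_axis(cls_p, best_c[..., None], -1)[..., 0]
        keep = score >= conf_threshold if conf_threshold > 0 else score >= -1
        for n in range(N):
            m = keep[n]
            if not m.any():
                continue
            rows[n].append(np.column_stack([
                score[n][m], xy[n][m] / size, wh[n][m] / size,
                best_c[n][m]]))
    per_image = []
    for n in range(N):
        if not rows[n]:
            per_image.append([])
            continue
        cand = np.concatenate(rows[n])
        cand = cand[cand[:, 3] > 0]
        cand = cand[cand[:, 4] > 0]
        if len(cand) > max_det:
            cand = cand[np.argsort(-cand[:, 0], kind="stable")[:max_det]]
        per_image.append([
            Detection(BoxXYWHN(float(cx), float(cy), float(w_), float(h_)),
                      int(c), float(s))
            for s, cx, cy, w_, h_, c in cand])
    return per_image


def encode_targets(boxes_xywh: np.ndarray, cls_ids, anchors: AnchorSet,
                   img_size: int, num_classes: int,
                   obj_logit: float = 8.0) -> list:
    """Inverse of :func:`decode` for boxes placed at their natural anchor.

    Each normalized (cx, cy, w, h) box is written into the grid cell/anchor
    whose prior best matches it.  Returns raw per-scale maps for one image.
    Boxes whose wh/anchor ratio leaves sigmoid's (0, 1) range are skipped.
    """
    boxes = np.atleast_2d(np.asarray(boxes_xywh, dtype=np.float64))
    anc = anchors.as_array()
    no = 5 + num_classes
    raws = [np.full((1, 3 * no, img_size // s, img_size // s), -12.0,
                    dtype=np.float32) for s in anchors.strides]
    for box, c in zip(boxes, np.atleast_1d(cls_ids)):
        wh_px = box[2:4] * img_size
        r = wh_px[None, None, :] / anc
        fit = np.maximum(r, 1 / r).max(axis=2)
        si, ai = np.unravel_index(fit.argmin(), fit.shape)
        stride = anchors.strides[si]
        H = img_size // stride
        gx, gy = box[0] * H, box[1] * H
        gi, gj = int(gx), int(gy)
        txy = (np.array([gx - gi, gy - gj]) + 0.5) / 2.0
        twh = np.sqrt(wh_px / anc[si, ai]) / 2.0
        if not ((0 < txy) & (txy < 1)).all() or not ((0 < twh) & (twh < 1)).all():
            continue
        view = raws[si].reshape(1, 3, no, H, H)
        logit = lambda p: float(np.log(p / (1 - p)))
        view[0, ai, 0, gj, gi] = logit(txy[0])
        view[0, ai, 1, gj, gi] = logit(txy[1])
        view[0, ai, 2, gj, gi] = logit(twh[0])
        view[0, ai, 3, gj, gi] = logit(twh[1])
        view[0, ai, 4, gj, gi] = obj_logit
        view[0, ai, 5 + int(c), gj, gi] = obj_logit
    return raws


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (n,4) and (m,4) corner boxes."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    tl = np.maximum(a[:, None, :2], b[None, :, :2])
    br = np.minimum(a[:, None, 2:], b[None, :, 2:])
    inter = np.clip(br - tl, 0, None).prod(axis=2)
    area_a = np.clip(a[:, 2:] - a[:, :2], 0, None).prod(axis=1)
    area_b = np.clip(b[:, 2:] - b[:, :2], 0, None).prod(axis=1)
    return inter / np.maximum(area_a[:, None] + area_b[None, :] - inter, 1e-12)


def nms(detections: list, iou_threshold: float = DEFAULT_IOU) -> list:
    """Greedy class-aware non-maximum suppression.

    Detections are visited in descending score (ties: larger area first,
    then input order); a detection is dropped when a kept detection of the
    same class overlaps it above ``iou_threshold``.
    """
    if not detections:
        return []
    boxes = np.array([d.xyxy() for d in detections])
    areas = np.clip(boxes[:, 2:] - boxes[:, :2], 0, None).prod(axis=1)
    classes = np.array([d.class_id for d in detections])
    iou = box_iou_xyxy(boxes, boxes)
    order = sorted(range(len(detections)),
                   key=lambda i: (-detections[i].score, -areas[i], i))
    kept: list[int] = []
    for i in order:
        if not kept:
            kept.append(i)
            continue
        k = np.asarray(kept)
        same = classes[k] == classes[i]
        if not (iou[i, k[same]] > iou_threshold).any():
            kept.append(i)
    return [detections[i] for i in kept]


def letterbox(img: np.ndarray, new_size: int = 640, color: int = 114):
    """Aspect-preserving resize + pad to a square canvas.

    Returns (padded image, scale ratio, (dw, dh) padding offsets in pixels).
    Nearest-neighbour resampling keeps this dependency-free and exact.
    """
    h, w = img.shape[:2]
    r = min(new_size / h, new_size / w)
    nh, nw = int(round(h * r)), int(round(w * r))
    ys = (np.arange(nh) / r).astype(int).clip(0, h - 1)
    xs = (np.arange(nw) / r).astype(int).clip(0, w - 1)
    resized = img[ys][:, xs]
    out = np.full((new_size, new_size) + img.shape[2:], color, dtype=img.dtype)
    dh, dw = (new_size - nh) // 2, (new_size - nw) // 2
    out[dh:dh + nh, dw:dw + nw] = resized
    return out, r, (dw, dh)


def unletterbox_boxes(boxes_xyxy_px: np.ndarray, ratio: float, pad,
                      orig_hw) -> np.ndarray:
    """Map letterboxed-pixel corner boxes back to original-image pixels."""
    dw, dh = pad
    h, w = orig_hw
    b = np.asarray(boxes_xyxy_px, dtype=np.float64).copy()
    b[:, [0, 2]] = (b[:, [0, 2]] - dw) / ratio
    b[:, [1, 3]] = (b[:, [1, 3]] - dh) / ratio
    b[:, [0, 2]] = b[:, [0, 2]].clip(0, w)
    b[:, [1, 3]] = b[:, [1, 3]].clip(0, h)
    return b


def time_inference(model, image: np.ndarray, repeats: int = 10,
                   warmup: int = 2, conf: float = DEFAULT_CONF,
                   iou: float = DEFAULT_IOU) -> TimingReport:
    """Mean per-stage wall time (ms) and the resulting throughput.

    Hardware-dependent by nature; reported for transparency, not as a
    comparable benchmark.
    """
    from .nn.autograd import no_grad

    model.eval()
    anchors = model.config.anchors
    tp = ti = tpo = 0.0
    for it in range(warmup + repeats):
        t0 = time.perf_counter()
        lb, _, _ = letterbox(image, model.config.img_size)
        x = lb.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
        t1 = time.perf_counter()
        with no_grad():
            raws = model(x)
        t2 = time.perf_counter()
        dets = decode(raws, anchors, conf)
        [nms(d, iou) for d in dets]
        t3 = time.perf_counter()
        if it >= warmup:
            tp += t1 - t0
            ti += t2 - t1
            tpo += t3 - t2
    k = 1000.0 / repeats
    return TimingReport(tp * k, ti * k, tpo * k)


# -- writers ----------------------------------------------------------------

def detections_to_jsonl(dets: list, path=None) -> str:
    lines = [json.dumps({"class_id": d.class_id, "score": round(d.score, 6),
                         "cx": d.box.cx, "cy": d.box.cy,
                         "w": d.box.w, "h": d.box.h}) for d in dets]
    s = "\n".join(lines) + ("\n" if lines else "")
    if path:
        with open(path, "w") as f:
            f.write(s)
    return s


def detections_to_yolo_txt(dets: list, path=None) -> str:
    lines = [f"{d.class_id} {d.box.cx:.6f} {d.box.cy:.6f} "
             f"{d.box.w:.6f} {d.box.h:.6f} {d.score:.6f}" for d in dets]
    s = "\n".join(lines) + ("\n" if lines else "")
    if path:
        with open(path, "w") as f:
            f.write(s)
    return s


def render_detections(img: np.ndarray, dets: list, class_names=None,
                      path=None):
    """Draw boxes + labels on an image (PIL), for visual inspection."""
    from PIL import Image, ImageDraw

    im = Image.fromarray(img)
    draw = ImageDraw.Draw(im)
    h, w = img.shape[:2]
    palette = [(230, 60, 60), (60, 180, 60), (60, 100, 230), (230, 180, 40),
               (180, 60, 230), (40, 200, 200), (240, 120, 40)]
    for d in dets:
        x1, y1, x2, y2 = d.xyxy(w, h)
        color = palette[d.class_id % len(palette)]
        draw.rectangle([x1, y1, x2, y2], outline=color, width=2)
        name = (class_names[d.class_id] if class_names else str(d.class_id))
        draw.text((x1 + 2, max(y1 - 10, 0)), f"{name} {d.score:.2f}",
                  fill=color)
    if path:
        im.save(path)
    return im
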