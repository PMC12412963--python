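"""Detection accuracy (precision, recall, AP/mAP) and count analysis.

``P = TP/(TP+FP)``, ``R = TP/(TP+FN)``; AP integrates the precision-recall
curve by 101-point interpolation and mAP averages AP over classes with at
least one ground truth, at an IoU match threshold of 0.5.

Count analysis compares per-image predicted vs. true object counts via
MAE, RMSE and the coefficient of determination R^2.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field

import numpy as np

from .postprocess import Detection, box_iou_xyxy


@dataclass
class MetricResult:
    num_classes: int
    tp: np.ndarray        # per-class true positives
    fp: np.ndarray
    fn: np.ndarray
    ap: np.ndarray        # per-class AP (nan where no ground truth)
    precision: np.ndarray
    recall: np.ndarray
    map50: float = field(init=False)

    def __post_init__(self):
        valid = ~np.isnan(self.ap)
        self.map50 = float(self.ap[valid].mean()) if valid.any() else 0.0

    def per_class_table(self, class_names=None, path=None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["class", "tp", "fp", "fn", "precision", "recall", "ap50"])
        for c in range(self.num_classes):
            name = class_names[c] if class_names else str(c)
            ap = "" if math.isnan(self.ap[c]) else f"{self.ap[c]:.4f}"
            w.writerow([name, int(self.tp[c]), int(self.fp[c]),
                        int(self.fn[c]), f"{self.precision[c]:.4f}",
                        f"{self.recall[c]:.4f}", ap])
        w.writerow(["mAP50", "", "", "", "", "", f"{self.map50:.4f}"])
        s = buf.getvalue()
        if path:
            with open(path, "w") as f:
                f.write(s)
        return s


@dataclass
class CountReport:
    true_counts: np.ndarray
    predicted_counts: np.ndarray
    mae: float
    rmse: float
    r2: float
    mean_true: float

    def to_csv(self, path=None) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["image", "true_count", "predicted_count"])
        for i, (y, yh) in enumerate(zip(self.true_counts,
                                        self.predicted_counts)):
            w.writerow([i, int(y), int(yh)])
        w.writerow(["MAE", f"{self.mae:.4f}", ""])
        w.writerow(["RMSE", f"{self.rmse:.4f}", ""])
        w.writerow(["R2", f"{self.r2:.4f}", ""])
        s = buf.getvalue()
        if path:
            with open(path, "w") as f:
                f.write(s)
        return s


def _to_xyxy_cls_score(dets):
    """Accept Detection lists or (n, 6) arrays [x1 y1 x2 y2 score cls]."""
    if len(dets) == 0:
        return np.empty((0, 6))
    if isinstance(dets[0], Detection):
        return np.array([[*d.xyxy(), d.score, d.class_id] for d in dets])
    return np.atleast_2d(np.asarray(dets, dtype=np.float64))


def _gt_to_xyxy_cls(gts):
    """Accept (n, 5) arrays [cls cx cy w h] (normalized) or corner+cls."""
    g = np.atleast_2d(np.asarray(gts, dtype=np.float64))
    if g.size == 0:
        return np.empty((0, 5))
    cls = g[:, 0]
    cx, cy, w, h = g[:, 1], g[:, 2], g[:, 3], g[:, 4]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2, cls],
                    axis=1)


def match_detections(detections, ground_truths, iou_threshold: float = 0.5):
    """Greedy score-descending one-to-one matching per class (one image).

    Returns (tp_flags, scores, classes, n_gt_per_class): ``tp_flags[i]`` says
    whether the i-th detection (original order) matched an unused ground
    truth of its own class at IoU >= threshold.
    """
    d = _to_xyxy_cls_score(detections)
    g = _gt_to_xyxy_cls(ground_truths)
    tp = np.zeros(len(d), dtype=bool)
    used = np.zeros(len(g), dtype=bool)
    order = np.argsort(-d[:, 4], kind="stable") if len(d) else []
    for i in order:
        same = np.nonzero((g[:, 4] == d[i, 5]) & ~used)[0]
        if len(same) == 0:
            continue
        ious = box_iou_xyxy(d[i, :4], g[same, :4])[0]
        j = ious.argmax()
        if ious[j] >= iou_threshold:
            tp[i] = True
            used[same[j]] = True
    return tp, d[:, 4], d[:, 5].astype(int), g[:, 4].astype(int)


def average_precision(tp_flags, scores, n_truths: int,
                      n_points: int = 101) -> float:
    """AP by interpolated integration of the precision-recall curve.

    ``tp_flags``/``scores`` cover every detection of one class over the
    dataset; detections are ranked by score before accumulation.
    """
    if n_truths == 0:
        return float("nan")
    tp_flags = np.asarray(tp_flags, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp_c = np.cumsum(tp_flags[order])
    fp_c = np.cumsum(1.0 - tp_flags[order])
    recall = tp_c / n_truths
    precision = tp_c / np.maximum(tp_c + fp_c, 1e-12)
    # precision envelope, then sample at evenly spaced recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    r_pts = np.linspace(0, 1, n_points)
    idx = np.searchsorted(recall, r_pts, side="left")
    p_at = np.where(idx < len(env), env[np.minimum(idx, len(env) - 1)], 0.0)
    return float(p_at.mean())


def map50(per_class_aps) -> float:
    aps = np.asarray(per_class_aps, dtype=float)
    valid = ~np.isnan(aps)
    return float(aps[valid].mean()) if valid.any() else 0.0


def evaluate_detections(preds_per_image, gts_per_image, num_classes: int,
                        iou_threshold: float = 0.5) -> MetricResult:
    """Dataset-level evaluation: greedy matching per image, AP per class."""
    if len(preds_per_image) != len(gts_per_image):
        raise ValueError("prediction/ground-truth image counts differ")
    all_tp, all_scores, all_cls = [], [], []
    n_gt = np.zeros(num_classes, dtype=int)
    for dets, gts in zip(preds_per_image, gts_per_image):
        tp, scores, cls, gt_cls = match_detections(dets, gts, iou_threshold)
        all_tp.append(tp)
        all_scores.append(scores)
        all_cls.append(cls)
        for c in gt_cls:
            n_gt[c] += 1
    tp = np.concatenate(all_tp) if all_tp else np.empty(0, bool)
    scores = np.concatenate(all_scores) if all_scores else np.empty(0)
    cls = np.concatenate(all_cls) if all_cls else np.empty(0, int)
    tp_pc = np.zeros(num_classes)
    fp_pc = np.zeros(num_classes)
    ap_pc = np.full(num_classes, np.nan)
    for c in range(num_classes):
        m = cls == c
        tp_pc[c] = tp[m].sum()
        fp_pc[c] = (~tp[m]).sum()
        if n_gt[c] > 0:
            ap_pc[c] = average_precision(tp[m], scores[m], n_gt[c])
    fn_pc = n_gt - tp_pc
    prec = np.divide(tp_pc, tp_pc + fp_pc,
                     out=np.zeros(num_classes), where=(tp_pc + fp_pc) > 0)
    rec = np.divide(tp_pc, n_gt, out=np.zeros(num_classes), where=n_gt > 0)
    return MetricResult(num_classes, tp_pc, fp_pc, fn_pc, ap_pc, prec, rec)


def count_analysis(true_counts, predicted_counts) -> CountReport:
    """MAE / RMSE / R^2 agreement between per-image counts."""
    y = np.asarray(true_counts, dtype=np.float64)
    yh = np.asarray(predicted_counts, dtype=np.float64)
    if y.shape != yh.shape:
        raise ValueError("count vectors must have equal length")
    if y.size < 2:
        raise ValueError("need at least two images for count analysis")
    if (y < 0).any() or (yh < 0).any():
        raise ValueError("counts must be non-negative")
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant true counts")
    resid = y - yh
    mae = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid**2).mean()))
    r2 = float(1.0 - (resid**2).sum() / ss_tot)
    return CountReport(y.astype(int), yh.astype(int), mae, rmse, r2,
                       float(y.mean()))


def counts_from_detections(dets_per_image, per_class: bool = False,
                           num_classes: int | None = None):
    """Per-image object counts from detection lists.

    ``per_class=False`` pools all classes into one count per image;
    ``per_class=True`` returns an (images, classes) matrix.
    """
    if not per_class:
        return np.array([len(d) for d in dets_per_image])
    if num_classes is None:
        raise ValueError("num_classes required for per-class counts")
    out = np.zeros((len(dets_per_image), num_classes), dtype=int)
    for i, dets in enumerate(dets_per_image):
        for d in dets:
            out[i, d.class_id] += 1
    return out
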