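"""Detection losses: CIoU box regression, BCE objectness/classification,
and the anchor-ratio target assignment that feeds them.

The box loss is the complete-IoU form

    L = 1 - IoU + rho^2(b, b_gt) / c^2 + alpha * v,

where ``rho`` is the distance between box centers, ``c`` the diagonal of the
smallest enclosing box, ``v = (4/pi^2) (arctan(w_gt/h_gt) - arctan(w/h))^2``
the aspect-ratio penalty and ``alpha = v / ((1 - IoU) + v)`` its trade-off
weight (treated as a constant during differentiation, as is standard).

Assignment follows the anchor-based convention: a ground-truth box matches
every anchor whose width and height ratios lie within [1/4, 4], in its own
grid cell plus the two nearest neighbour cells (0.5-cell rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import AnchorSet
from .nn import autograd as ag
from .nn.autograd import Tensor

EPS = 1e-7

# loss weights (box, objectness, class) and per-scale objectness balance
DEFAULT_WEIGHTS = {"box": 0.05, "obj": 1.0, "cls": 0.5}
OBJ_BALANCE = (4.0, 1.0, 0.4)
ANCHOR_RATIO_THRESH = 4.0
NEIGHBOR_OFFSET = 0.5


@dataclass(frozen=True)
class BoxXYWHN:
    """Normalized center-format box: all fields are fractions of the image."""

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box dims must be positive")

    def to_corners(self):
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)

    def clipped(self) -> "BoxXYWHN":
        x1, y1, x2, y2 = (min(max(v, 0.0), 1.0) for v in self.to_corners())
        return BoxXYWHN((x1 + x2) / 2, (y1 + y2) / 2,
                        max(x2 - x1, EPS), max(y2 - y1, EPS))

    def as_array(self):
        return np.array([self.cx, self.cy, self.w, self.h], dtype=np.float32)


@dataclass
class LossBreakdown:
    box_loss: float
    obj_loss: float
    cls_loss: float
    total: Tensor  # weighted sum, differentiable

    @property
    def total_value(self) -> float:
        return float(self.total.data)


def _coerce_boxes(x, fmt):
    if isinstance(x, BoxXYWHN):
        x = x.as_array()
    if not isinstance(x, Tensor):
        x = Tensor(np.atleast_2d(np.asarray(x, dtype=np.float32)))
    if fmt == "xyxy":
        x1, y1, x2, y2 = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
        x = ag.stack([(x1 + x2) * 0.5, (y1 + y2) * 0.5, x2 - x1, y2 - y1], axis=-1)
    elif fmt != "xywh":
        raise ValueError("fmt must be 'xywh' or 'xyxy'")
    return x


def ciou_terms(pred: Tensor, target: Tensor):
    """CIoU loss and plain IoU for center-format (..., 4) boxes."""
    px, py, pw, ph = pred[..., 0], pred[..., 1], pred[..., 2], pred[..., 3]
    tx, ty, tw, th = target[..., 0], target[..., 1], target[..., 2], target[..., 3]
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw * 0.5, tx + tw * 0.5
    ty1, ty2 = ty - th * 0.5, ty + th * 0.5

    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.clamp(lo=0.0) * ih.clamp(lo=0.0)
    union = pw * ph + tw * th - inter + EPS
    iou = inter / union

    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + ch * ch + EPS
    rho2 = (tx - px) ** 2.0 + (ty - py) ** 2.0
    v = (4.0 / math.pi**2) * ((tw / (th + EPS)).atan() - (pw / (ph + EPS)).atan()) ** 2.0
    alpha = v.data / (1.0 - iou.data + v.data + EPS)  # constant in backward
    loss = 1.0 - iou + rho2 / c2 + v * alpha
    return loss, iou


def ciou_loss(pred, gt, fmt: str = "xywh"):
    """CIoU loss between boxes.  Accepts :class:`BoxXYWHN`, arrays or
    Tensors; returns a float for plain inputs, a Tensor for Tensor inputs."""
    tensor_in = isinstance(pred, Tensor) or isinstance(gt, Tensor)
    p = _coerce_boxes(pred, fmt)
    t = _coerce_boxes(gt, fmt)
    loss, _ = ciou_terms(p, t)
    if tensor_in:
        return loss
    out = loss.data
    return float(out.reshape(())) if out.size == 1 else out


def bce_loss(labels, probabilities) -> float:
    """Binary cross-entropy on post-sigmoid probabilities."""
    y = np.asarray(labels, dtype=np.float64).ravel()
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable mean BCE on raw logits (differentiable)."""
    t = np.asarray(targets, dtype=np.float32)
    return (logits.logaddexp0() - logits * t).mean()


@dataclass
class ScaleAssignment:
    """Index tensors for one prediction scale."""

    image: np.ndarray   # (M,) batch indices
    anchor: np.ndarray  # (M,) anchor indices within scale
    gj: np.ndarray      # (M,) grid rows
    gi: np.ndarray      # (M,) grid cols
    txy: np.ndarray     # (M,2) target centers, grid units
    twh: np.ndarray     # (M,2) target dims, grid units
    cls: np.ndarray     # (M,) class indices
    anchor_wh: np.ndarray  # (M,2) matched anchor dims, grid units

    def __len__(self):
        return len(self.image)


def assign_targets(labels: np.ndarray, anchors: AnchorSet, grid_shapes,
                   ratio_thresh: float = ANCHOR_RATIO_THRESH,
                   neighbor: float = NEIGHBOR_OFFSET) -> list:
    """Match normalized labels (n, 6: img cls cx cy w h) to anchors/cells.

    Returns one :class:`ScaleAssignment` per scale.  Empty label sets give
    empty assignments.
    """
    labels = np.asarray(labels, dtype=np.float64).reshape(-1, 6)
    anc = anchors.as_array()  # (3, na, 2) pixels
    out = []
    for si, ((gh, gw), stride) in enumerate(zip(grid_shapes, anchors.strides)):
        a_grid = anc[si] / stride  # anchor dims in grid units
        na = len(a_grid)
        if len(labels) == 0:
            out.append(ScaleAssignment(*[np.empty(0, dtype=np.int64)] * 4,
                                       np.empty((0, 2)), np.empty((0, 2)),
                                       np.empty(0, dtype=np.int64),
                                       np.empty((0, 2))))
            continue
        gxy = labels[:, 2:4] * np.array([gw, gh])   # grid units
        gwh = labels[:, 4:6] * np.array([gw, gh])
        r = gwh[:, None, :] / a_grid[None, :, :]    # (n, na, 2)
        ok = np.maximum(r, 1.0 / r).max(axis=2) < ratio_thresh
        ti, ai = np.nonzero(ok)
        if len(ti) == 0:
            out.append(ScaleAssignment(*[np.empty(0, dtype=np.int64)] * 4,
                                       np.empty((0, 2)), np.empty((0, 2)),
                                       np.empty(0, dtype=np.int64),
                                       np.empty((0, 2))))
            continue
        # neighbour-cell replication
        xy = gxy[ti]
        xi = np.array([gw, gh]) - xy
        left = (xy % 1 < neighbor) & (xy > 1)
        right = (xi % 1 < neighbor) & (xi > 1)
        keep = np.stack([np.ones(len(ti), dtype=bool),
                         left[:, 0], left[:, 1], right[:, 0], right[:, 1]])
        offsets = np.array([[0, 0], [-neighbor, 0], [0, -neighbor],
                            [neighbor, 0], [0, neighbor]])
        idx_rep = np.tile(np.arange(len(ti)), 5).reshape(5, -1)[keep]
        off_rep = np.repeat(offsets[:, None, :], len(ti), axis=1)[keep]
        sel_t, sel_a = ti[idx_rep], ai[idx_rep]
        sel_xy = gxy[sel_t] + off_rep
        gij = sel_xy.astype(np.int64)
        gi = np.clip(gij[:, 0], 0, gw - 1)
        gj = np.clip(gij[:, 1], 0, gh - 1)
        out.append(ScaleAssignment(
            image=labels[sel_t, 0].astype(np.int64),
            anchor=sel_a.astype(np.int64), gj=gj, gi=gi,
            txy=gxy[sel_t], twh=gwh[sel_t],
            cls=labels[sel_t, 1].astype(np.int64),
            anchor_wh=a_grid[sel_a]))
    return out


def detection_loss(raws, labels, anchors: AnchorSet, num_classes: int,
                   weights: dict | None = None) -> LossBreakdown:
    """Composite loss over raw multi-scale head outputs.

    ``raws`` are the pre-sigmoid per-scale maps (N, 3*(5+nc), H, W); labels
    are normalized (n, 6) rows.  Box and class terms average over assigned
    anchor/cell pairs; the objectness term covers every cell, with assigned
    cells targeted at the (detached) prediction IoU.
    """
    w = dict(DEFAULT_WEIGHTS, **(weights or {}))
    nc = num_classes
    no = 5 + nc
    grid_shapes = [(r.shape[2], r.shape[3]) for r in raws]
    assigns = assign_targets(labels, anchors, grid_shapes)

    lbox_terms, lcls_terms, lobj = [], [], None
    n_pairs = 0
    for raw, asg, balance in zip(raws, assigns, OBJ_BALANCE):
        N, _, H, W = raw.shape
        pred = raw.reshape(N, 3, no, H, W).transpose(0, 1, 3, 4, 2)  # N,3,H,W,no
        tobj = np.zeros((N, 3, H, W), dtype=np.float32)
        if len(asg):
            ps = pred[(asg.image, asg.anchor, asg.gj, asg.gi)]  # (M, no)
            sig = ps.sigmoid()
            cell = np.stack([asg.gi, asg.gj], axis=1).astype(np.float32)
            pxy = sig[:, 0:2] * 2.0 - 0.5 + cell
            pwh = (sig[:, 2:4] * 2.0) ** 2.0 * asg.anchor_wh.astype(np.float32)
            pbox = ag.cat([pxy, pwh], axis=1)
            tbox = np.concatenate([asg.txy, asg.twh], axis=1).astype(np.float32)
            closs, iou = ciou_terms(pbox, Tensor(tbox))
            lbox_terms.append(closs.sum())
            n_pairs += len(asg)
            np.maximum.at(tobj, (asg.image, asg.anchor, asg.gj, asg.gi),
                          np.clip(iou.data, 0.0, None))
            if nc > 1:
                tcls = np.zeros((len(asg), nc), dtype=np.float32)
                tcls[np.arange(len(asg)), asg.cls] = 1.0
                lcls_terms.append(bce_with_logits(ps[:, 5:], tcls) * len(asg))
        obj_logits = pred[..., 4]
        term = bce_with_logits(obj_logits, tobj) * balance
        lobj = term if lobj is None else lobj + term

    zero = Tensor(np.zeros(()))
    lbox = (sum(lbox_terms[1:], lbox_terms[0]) * (1.0 / n_pairs)
            if n_pairs else zero)
    lcls = (sum(lcls_terms[1:], lcls_terms[0]) * (1.0 / n_pairs)
            if lcls_terms else zero)
    total = w["box"] * lbox + w["obj"] * lobj + w["cls"] * lcls
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"non-finite loss: box={float(lbox.data)} obj={float(lobj.data)} "
            f"cls={float(lcls.data)}")
    return LossBreakdown(float(lbox.data), float(lobj.data),
                         float(lcls.data), total)
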