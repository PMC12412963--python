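"""Detector assembly: scaled backbone, PAFPN neck, coupled anchor head.

The network follows the familiar one-stage layout.  A ten-slot backbone
(stem, one plain downsampling CBS, four C-slots interleaved with three MPC
downsamplers, and SPPR on top) feeds a path-aggregation neck arranged like
YOLOv8's (upsample-concat-block twice top-down, then strided-CBS-concat-
block twice bottom-up) with C2fR everywhere.  A coupled head — one 1x1
convolution per scale — emits ``3 * (5 + nc)`` channels at strides 8/16/32.

Five ablation variants differ only in which block fills the four backbone
C-slots:

========  ====================================
variant   C-slots (layers 2 / 4 / 6 / 8)
========  ====================================
cf1       C2f, C2f, C2f, C2f
cf2       C3,  C2f, C3,  C2f
cf3       C3,  C2fR, C3, C2fR
cf4       C3,  C3,  C3,  C3
cf5       C2fR, C2fR, C2fR, C2fR  (the full detector)
========  ====================================
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .blocks import (CBS, MPC, SPPR, BlockKind, BlockSpec, build_slot)
from .nn import autograd as ag
from .nn.layers import Conv2d, Module, Upsample

# anchor priors (pixels at 640 input), strides 8/16/32 — YOLOv5 defaults
DEFAULT_ANCHORS = (
    ((10, 13), (16, 30), (33, 23)),
    ((30, 61), (62, 45), (59, 119)),
    ((116, 90), (156, 198), (373, 326)),
)
STRIDES = (8, 16, 32)

VARIANT_SLOTS = {
    "cf1": ("C2f", "C2f", "C2f", "C2f"),
    "cf2": ("C3", "C2f", "C3", "C2f"),
    "cf3": ("C3", "C2fR", "C3", "C2fR"),
    "cf4": ("C3", "C3", "C3", "C3"),
    "cf5": ("C2fR", "C2fR", "C2fR", "C2fR"),
}


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


@dataclass(frozen=True)
class AnchorSet:
    """Per-scale anchor (w, h) pixel pairs at strides 8/16/32."""

    anchors: tuple = DEFAULT_ANCHORS
    strides: tuple = STRIDES

    def __post_init__(self):
        if len(self.anchors) != len(self.strides):
            raise ValueError("one anchor group per stride required")
        for grp in self.anchors:
            if any(w <= 0 or h <= 0 for w, h in grp):
                raise ValueError("anchor dims must be positive")
            areas = [w * h for w, h in grp]
            if areas != sorted(areas):
                raise ValueError("anchors must be sorted by area within scale")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.anchors, dtype=np.float32)  # (3, na, 2)

    @property
    def num_per_scale(self) -> int:
        return len(self.anchors[0])


@dataclass
class ModelConfig:
    num_classes: int = 7
    depth_multiple: float = 0.33
    width_multiple: float = 0.25
    img_size: int = 640
    variant: str = "cf5"
    anchors: AnchorSet = field(default_factory=AnchorSet)
    base_channels: tuple = (64, 128, 256, 512, 1024)
    base_repeats: int = 3  # per C-slot, before depth scaling

    def __post_init__(self):
        if self.variant not in VARIANT_SLOTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.img_size % 32:
            raise ValueError("img_size must be divisible by 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be positive")

    @property
    def channels(self) -> tuple:
        return tuple(make_divisible(c * self.width_multiple)
                     for c in self.base_channels)

    @property
    def repeats(self) -> int:
        return max(round(self.base_repeats * self.depth_multiple), 1)


class Detector(Module):
    """The assembled network.  ``forward`` returns raw per-scale maps of
    shape (N, 3*(5+nc), H_s, W_s); decoding lives in :mod:`postprocess`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c0, c1, c2, c3, c4 = config.channels
        n = config.repeats
        slots = VARIANT_SLOTS[config.variant]
        no = 3 * (5 + config.num_classes)
        self.num_outputs = no

        # backbone
        self.stem_down = CBS(3, c0, 3, 2, rng=rng)
        self.stem_refine = CBS(c0, c0, 3, 1, rng=rng)
        self.down1 = CBS(c0, c1, 3, 2, rng=rng)
        self.slot2 = build_slot(slots[0], c1, c1, n, rng=rng)
        self.down3 = MPC(c1, c2, rng=rng)
        self.slot4 = build_slot(slots[1], c2, c2, n, rng=rng)
        self.down5 = MPC(c2, c3, rng=rng)
        self.slot6 = build_slot(slots[2], c3, c3, n, rng=rng)
        self.down7 = MPC(c3, c4, rng=rng)
        self.slot8 = build_slot(slots[3], c4, c4, n, rng=rng)
        self.spp = SPPR(c4, c4, rng=rng)

        # neck (PAFPN, C2fR everywhere, no shortcut semantics to track)
        self.up = Upsample()
        self.neck1 = build_slot("C2fR", c4 + c3, c3, n, rng=rng)
        self.neck2 = build_slot("C2fR", c3 + c2, c2, n, rng=rng)
        self.pan_down1 = CBS(c2, c2, 3, 2, rng=rng)
        self.neck3 = build_slot("C2fR", c2 + c3, c3, n, rng=rng)
        self.pan_down2 = CBS(c3, c3, 3, 2, rng=rng)
        self.neck4 = build_slot("C2fR", c3 + c4, c4, n, rng=rng)

        # coupled head: one 1x1 conv per scale
        self.head = [Conv2d(c, no, 1, 1, bias=True, rng=rng)
                     for c in (c2, c3, c4)]
        self._init_head_biases()

    def _init_head_biases(self):
        """Prior-aware head bias initialisation (objectness ~ 8 objects per
        640-image; class priors ~ 0.6/nc) — stabilises early training."""
        nc = self.config.num_classes
        for conv, s in zip(self.head, STRIDES):
            b = conv.bias.data.reshape(3, 5 + nc)
            b[:, 4] += np.log(8.0 / (640.0 / s) ** 2)
            b[:, 5:] += np.log(0.6 / (nc - 0.99)) if nc > 1 else 0.0
            conv.bias.data = b.reshape(-1)

    def forward(self, x):
        if not isinstance(x, ag.Tensor):
            x = ag.Tensor(x)
        if x.shape[1] != 3:
            raise ValueError("expected 3-channel NCHW input")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("spatial dims must be divisible by 32")
        x = self.stem_refine(self.stem_down(x))
        x = self.down1(x)
        x = self.slot2(x)
        x = self.down3(x)
        p3 = self.slot4(x)
        x = self.down5(p3)
        p4 = self.slot6(x)
        x = self.down7(p4)
        x = self.slot8(x)
        p5 = self.spp(x)

        n1 = self.neck1(ag.cat([self.up(p5), p4], axis=1))
        n2 = self.neck2(ag.cat([self.up(n1), p3], axis=1))
        n3 = self.neck3(ag.cat([self.pan_down1(n2), n1], axis=1))
        n4 = self.neck4(ag.cat([self.pan_down2(n3), p5], axis=1))
        return [h(f) for h, f in zip(self.head, (n2, n3, n4))]

    # -- description / persistence ----------------------------------------
    def layer_table(self) -> list:
        c0, c1, c2, c3, c4 = self.config.channels
        n = self.config.repeats
        s = VARIANT_SLOTS[self.config.variant]
        no = self.num_outputs
        K = BlockKind

        def spec(kind, ci, co, k=1, st=1, r=1):
            return BlockSpec(K(kind), ci, co, k, st, r)

        return [
            ("stem", spec("CBS", 3, c0, 3, 2)),
            ("stem_refine", spec("CBS", c0, c0, 3, 1)),
            ("down1", spec("CBS", c0, c1, 3, 2)),
            ("slot2", spec(s[0], c1, c1, 1, 1, n)),
            ("down3", spec("MPC", c1, c2, 3, 2)),
            ("slot4", spec(s[1], c2, c2, 1, 1, n)),
            ("down5", spec("MPC", c2, c3, 3, 2)),
            ("slot6", spec(s[2], c3, c3, 1, 1, n)),
            ("down7", spec("MPC", c3, c4, 3, 2)),
            ("slot8", spec(s[3], c4, c4, 1, 1, n)),
            ("spp", spec("SPPR", c4, c4, 5, 1)),
            ("neck1", spec("C2fR", c4 + c3, c3, 1, 1, n)),
            ("neck2", spec("C2fR", c3 + c2, c2, 1, 1, n)),
            ("pan_down1", spec("CBS", c2, c2, 3, 2)),
            ("neck3", spec("C2fR", c2 + c3, c3, 1, 1, n)),
            ("pan_down2", spec("CBS", c3, c3, 3, 2)),
            ("neck4", spec("C2fR", c3 + c4, c4, 1, 1, n)),
            ("head_p3", spec("Head", c2, no)),
            ("head_p4", spec("Head", c3, no)),
            ("head_p5", spec("Head", c4, no)),
        ]

    def to_yaml(self) -> str:
        rows = [
            {"name": name, "kind": sp.kind.value, "in": sp.in_channels,
             "out": sp.out_channels, "kernel": sp.kernel,
             "stride": sp.stride, "repeats": sp.repeats}
            for name, sp in self.layer_table()
        ]
        meta = {"variant": self.config.variant,
                "num_classes": self.config.num_classes,
                "depth_multiple": self.config.depth_multiple,
                "width_multiple": self.config.width_multiple,
                "img_size": self.config.img_size}
        return yaml.safe_dump({"model": meta, "layers": rows}, sort_keys=False)


def build_model(config: ModelConfig, seed: int = 0) -> Detector:
    return Detector(config, seed=seed)


def save_checkpoint(model: Detector, path):
    sd = model.state_dict()
    cfg = model.config
    meta = json.dumps({
        "num_classes": cfg.num_classes, "depth_multiple": cfg.depth_multiple,
        "width_multiple": cfg.width_multiple, "img_size": cfg.img_size,
        "variant": cfg.variant,
        "anchors": [list(map(list, g)) for g in cfg.anchors.anchors],
    })
    buf = io.BytesIO()
    np.savez(buf, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **sd)
    with open(path, "wb") as f:
        f.write(buf.getvalue())


def load_checkpoint(path) -> Detector:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__config__"]).decode())
        sd = {k: z[k] for k in z.files if k != "__config__"}
    anchors = AnchorSet(tuple(tuple(tuple(a) for a in g) for g in meta.pop("anchors")))
    cfg = ModelConfig(anchors=anchors, **meta)
    model = Detector(cfg)
    model.load_state_dict(sd)
    return model


# ---------------------------------------------------------------------------
# anchor estimation
# ---------------------------------------------------------------------------

def _wh_iou(wh: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """IoU of (n,2) box dims vs (k,2) anchor dims, both corner-aligned."""
    inter = (np.minimum(wh[:, None, 0], centers[None, :, 0])
             * np.minimum(wh[:, None, 1], centers[None, :, 1]))
    union = (wh[:, 0] * wh[:, 1])[:, None] + (centers[:, 0] * centers[:, 1])[None] - inter
    return inter / np.maximum(union, 1e-12)


def kmeans_anchors(wh: np.ndarray, k: int, iters: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Lloyd k-means under IoU distance on box dimensions; centers sorted
    by area."""
    wh = np.asarray(wh, dtype=np.float64)
    if len(wh) < k:
        raise ValueError(f"need at least {k} boxes, got {len(wh)}")
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), k, replace=False)].copy()
    assign = None
    for _ in range(iters):
        new_assign = _wh_iou(wh, centers).argmax(axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = wh[assign == j]
            if len(sel):
                centers[j] = sel.mean(axis=0)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return centers[order]


def best_possible_recall(wh: np.ndarray, anchors_flat: np.ndarray,
                         ratio_thresh: float = 4.0) -> float:
    """Fraction of boxes matched by some anchor under the w/h-ratio rule."""
    r = wh[:, None, :] / anchors_flat[None, :, :]
    worst = np.maximum(r, 1.0 / r).max(axis=2)  # (n, k)
    return float((worst.min(axis=1) < ratio_thresh).mean())


def autoanchor(labels: np.ndarray, k: int = 9, img_size: int = 640,
               seed: int = 0) -> AnchorSet:
    """Estimate anchors from normalized labels (n, >=5 cols: cls cx cy w h).

    Falls back to the default anchor table when the k-means result does not
    improve best-possible recall.
    """
    if k != 9:
        raise ValueError("autoanchor builds 3 scales x 3 anchors (k=9)")
    labels = np.asarray(labels, dtype=np.float64)
    wh = labels[:, 3:5] * img_size
    if len(wh) < k:
        raise ValueError(f"need at least {k} labelled boxes, got {len(wh)}")
    default_flat = np.asarray(DEFAULT_ANCHORS, dtype=np.float64).reshape(-1, 2)
    scale = img_size / 640.0
    default_flat = default_flat * scale
    centers = kmeans_anchors(wh, k, seed=seed)
    if best_possible_recall(wh, centers) <= best_possible_recall(wh, default_flat):
        centers = default_flat[np.argsort(default_flat[:, 0] * default_flat[:, 1])]
    groups = []
    for g in range(3):
        grp = centers[3 * g:3 * g + 3]
        grp = grp[np.argsort(grp[:, 0] * grp[:, 1])]
        groups.append(tuple((float(w), float(h)) for w, h in grp))
    return AnchorSet(tuple(groups))
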