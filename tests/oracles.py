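"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — per-layer arithmetic sums for
parameter counts, O(n^2) loops for NMS/matching, exhaustive enumeration for
anchor assignment — and shares no code with the package's own paths.
"""

import numpy as np

# ---------------------------------------------------------------------------
# parameter-count arithmetic: conv = i*k*k*o (+o bias), BN = 2 per channel
# ---------------------------------------------------------------------------

def conv_p(i, o, k, bias=False):
    return i * k * k * o + (o if bias else 0)


def cbs_p(i, o, k):
    return conv_p(i, o, k) + 2 * o


def mpc_p(i, o):
    c = o // 2
    return cbs_p(i, c, 1) + cbs_p(i, c, 1) + cbs_p(c, c, 3)


def c4_p(c):
    return cbs_p(c, 2 * c, 1) + 2 * cbs_p(c, c, 3) + cbs_p(2 * c, c, 1)


def c2fr_p(i, o, n):
    c = o // 2
    return (cbs_p(i, c, 1) + cbs_p(i, c, 1) + cbs_p(2 * c, o, 1)
            + n * c4_p(c))


def c3_p(i, o, n):
    c = o // 2
    return (2 * cbs_p(i, c, 1) + cbs_p(2 * c, o, 1)
            + n * (cbs_p(c, c, 1) + cbs_p(c, c, 3)))


def c2f_p(i, o, n):
    c = o // 2
    return (cbs_p(i, 2 * c, 1) + cbs_p((2 + n) * c, o, 1)
            + n * 2 * cbs_p(c, c, 3))


def sppr_p(i, o):
    c = i // 2
    return cbs_p(i, c, 1) + cbs_p(2 * c, o, 1)


def sppf_p(i, o):
    c = i // 2
    return cbs_p(i, c, 1) + cbs_p(4 * c, o, 1)


# ---------------------------------------------------------------------------
# brute-force NMS
# ---------------------------------------------------------------------------

def iou_xyxy(a, b):
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(ix2 - ix1, 0) * max(iy2 - iy1, 0)
    ar_a = max(a[2] - a[0], 0) * max(a[3] - a[1], 0)
    ar_b = max(b[2] - b[0], 0) * max(b[3] - b[1], 0)
    return inter / max(ar_a + ar_b - inter, 1e-12)


def nms_bruteforce(boxes, scores, classes, thresh):
    """Returns kept indices; greedy by (score desc, area desc, index)."""
    areas = [max(b[2] - b[0], 0) * max(b[3] - b[1], 0) for b in boxes]
    order = sorted(range(len(boxes)),
                   key=lambda i: (-scores[i], -areas[i], i))
    kept = []
    for i in order:
        if all(classes[i] != classes[j]
               or iou_xyxy(boxes[i], boxes[j]) <= thresh for j in kept):
            kept.append(i)
    return kept


# ---------------------------------------------------------------------------
# brute-force anchor assignment (one label, one scale at a time)
# ---------------------------------------------------------------------------

def assign_bruteforce(labels, anchors_px, strides, grid_shapes,
                      ratio=4.0, g=0.5):
    """Set of (scale, image, anchor, gj, gi, label_idx) tuples."""
    out = set()
    for si, ((gh, gw), stride) in enumerate(zip(grid_shapes, strides)):
        for li, lab in enumerate(labels):
            img, cls, cx, cy, w, h = lab
            gx, gy = cx * gw, cy * gh
            bw, bh = w * gw, h * gh
            for ai, (aw, ah) in enumerate(anchors_px[si]):
                aw, ah = aw / stride, ah / stride
                r = max(bw / aw, aw / bw, bh / ah, ah / bh)
                if r >= ratio:
                    continue
                cells = {(int(gx), int(gy))}
                fx, fy = gx % 1, gy % 1
                if fx < g and gx > 1:
                    cells.add((int(gx - g), int(gy)))
                if fy < g and gy > 1:
                    cells.add((int(gx), int(gy - g)))
                if (gw - gx) % 1 < g and (gw - gx) > 1:
                    cells.add((int(gx + g), int(gy)))
                if (gh - gy) % 1 < g and (gh - gy) > 1:
                    cells.add((int(gx), int(gy + g)))
                for ci, cj in cells:
                    out.add((si, int(img), ai,
                             min(max(cj, 0), gh - 1),
                             min(max(ci, 0), gw - 1), li))
    return out


# ---------------------------------------------------------------------------
# direct PR-curve integration (101-point)
# ---------------------------------------------------------------------------

def ap_bruteforce(tp_flags, scores, n_truths, n_points=101):
    order = np.argsort(-np.asarray(scores), kind="stable")
    tps = np.asarray(tp_flags, float)[order]
    ap = 0.0
    for r_level in np.linspace(0, 1, n_points):
        best = 0.0
        tp = fp = 0
        for f in tps:
            tp, fp = tp + f, fp + (1 - f)
            rec = tp / n_truths
            prec = tp / (tp + fp)
            if rec >= r_level:
                best = max(best, prec)
        ap += best / n_points
    return ap
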