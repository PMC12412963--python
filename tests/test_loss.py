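"""Loss closed forms, CIoU geometry, assignment vs. brute force, and the
composite loss contracts."""

import math

import numpy as np
import pytest

import oracles
from yolocf.loss import (BoxXYWHN, assign_targets, bce_loss, bce_with_logits,
                         ciou_loss, detection_loss)
from yolocf.model import AnchorSet, ModelConfig, build_model
from yolocf.nn.autograd import Tensor


# -- CIoU -------------------------------------------------------------------

def test_ciou_identical_boxes_zero():
    assert ciou_loss([0.5, 0.5, 0.2, 0.3], [0.5, 0.5, 0.2, 0.3]) \
        == pytest.approx(0.0, abs=1e-5)


def test_ciou_worked_corner_example():
    """Corner boxes (0,0,2,2) vs (1,1,3,3): IoU=1/7, rho2=2, c2=18, v=0
    -> 6/7 + 1/9."""
    got = ciou_loss([0, 0, 2, 2], [1, 1, 3, 3], fmt="xyxy")
    assert got == pytest.approx(6 / 7 + 1 / 9, abs=1e-4)


def test_ciou_at_least_one_minus_iou(rng):
    for _ in range(200):
        p = np.concatenate([rng.uniform(0.2, 0.8, 2), rng.uniform(0.05, 0.4, 2)])
        t = np.concatenate([rng.uniform(0.2, 0.8, 2), rng.uniform(0.05, 0.4, 2)])
        from yolocf.loss import ciou_terms
        loss, iou = ciou_terms(Tensor(p[None]), Tensor(t[None]))
        assert loss.data[0] >= (1 - iou.data[0]) - 1e-6
        assert 0 <= loss.data[0] <= 2.5


def test_ciou_reduces_to_one_minus_iou_when_centered_same_aspect():
    # same centers, same aspect ratio -> D = V = 0
    got = ciou_loss([0.5, 0.5, 0.2, 0.1], [0.5, 0.5, 0.4, 0.2])
    iou = (0.2 * 0.1) / (0.4 * 0.2)
    assert got == pytest.approx(1 - iou, abs=1e-5)


def test_box_type_validation():
    with pytest.raises(ValueError):
        BoxXYWHN(0.5, 0.5, 0.0, 0.1)
    b = BoxXYWHN(0.05, 0.5, 0.2, 0.2).clipped()
    assert b.to_corners()[0] == pytest.approx(0.0)


# -- BCE --------------------------------------------------------------------

@pytest.mark.parametrize("y,p,expect", [
    ([1.0], [0.999999], 0.0),
    ([1.0], [0.5], math.log(2)),
    ([1.0, 0.0], [0.9, 0.1], -math.log(0.9)),
])
def test_bce_closed_forms(y, p, expect):
    assert bce_loss(y, p) == pytest.approx(expect, abs=1e-4)


def test_bce_length_mismatch():
    with pytest.raises(ValueError):
        bce_loss([1, 0], [0.5])


def test_bce_matches_direct_expression(rng):
    y = rng.integers(0, 2, 500).astype(float)
    p = rng.uniform(1e-4, 1 - 1e-4, 500)
    direct = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert bce_loss(y, p) == pytest.approx(direct, abs=1e-7)


def test_bce_with_logits_matches_probability_form(rng):
    x = rng.normal(0, 2, 300).astype(np.float32)
    y = rng.integers(0, 2, 300).astype(np.float32)
    p = 1 / (1 + np.exp(-x.astype(np.float64)))
    assert float(bce_with_logits(Tensor(x), y).data) \
        == pytest.approx(bce_loss(y, p), abs=1e-5)


# -- assignment -------------------------------------------------------------

def _grids(img, strides=(8, 16, 32)):
    return [(img // s, img // s) for s in strides]


def test_assignment_anchor_sized_box_matches(anchors):
    # a box exactly equal to anchor (30,61) at stride 16, centered in a cell
    labels = np.array([[0, 0, 0.5 + 1 / 80, 0.5 + 1 / 80, 30 / 640, 61 / 640]])
    asg = assign_targets(labels, anchors, _grids(640))
    assert len(asg[1]) >= 1
    assert 0 in asg[1].anchor


def test_assignment_ratio_threshold_excludes(anchors):
    # box 5x wider than the widest anchor at a scale cannot match there
    labels = np.array([[0, 0, 0.5, 0.5, 5 * 373 / 640, 326 / 640]])
    asg = assign_targets(labels, anchors, _grids(640))
    assert all(len(a) == 0 for a in asg)


def test_assignment_empty_labels_ok(anchors):
    asg = assign_targets(np.empty((0, 6)), anchors, _grids(640))
    assert all(len(a) == 0 for a in asg)


@pytest.mark.parametrize("trial", range(20))
def test_assignment_equals_bruteforce(trial, anchors):
    """Vectorised assignment equals exhaustive rule enumeration."""
    rng = np.random.default_rng(2000 + trial)
    n = int(rng.integers(1, 12))
    labels = np.zeros((n, 6))
    labels[:, 0] = rng.integers(0, 3, n)
    labels[:, 1] = rng.integers(0, 7, n)
    labels[:, 2:4] = rng.uniform(0.05, 0.95, (n, 2))
    labels[:, 4:6] = rng.uniform(0.01, 0.6, (n, 2))
    grids = _grids(640)
    asg = assign_targets(labels, anchors, grids)
    got = set()
    for si, a in enumerate(asg):
        for b, ai, gj, gi in zip(a.image, a.anchor, a.gj, a.gi):
            got.add((si, int(b), int(ai), int(gj), int(gi)))
    want = {(si, img, ai, gj, gi) for (si, img, ai, gj, gi, _li)
            in oracles.assign_bruteforce(labels, anchors.as_array(),
                                         anchors.strides, grids)}
    assert got == want


# -- composite loss ---------------------------------------------------------

@pytest.fixture(scope="module")
def small_raws():
    m = build_model(ModelConfig(num_classes=7, img_size=96), seed=3)
    m.train()
    x = np.random.default_rng(5).random((2, 3, 96, 96), dtype=np.float32)
    return m, m(x)


def test_loss_empty_labels(small_raws):
    m, raws = small_raws
    lb = detection_loss(raws, np.empty((0, 6)), m.config.anchors, 7)
    assert lb.box_loss == 0.0 and lb.cls_loss == 0.0
    assert lb.obj_loss > 0.0
    assert lb.total_value == pytest.approx(lb.obj_loss, rel=1e-5)


def test_loss_weighted_sum(small_raws):
    m, raws = small_raws
    labels = np.array([[0, 3, 0.4, 0.5, 0.2, 0.25]])
    lb = detection_loss(raws, labels, m.config.anchors, 7)
    assert lb.total_value == pytest.approx(
        0.05 * lb.box_loss + 1.0 * lb.obj_loss + 0.5 * lb.cls_loss, rel=1e-4)
    assert lb.box_loss >= 0 and lb.cls_loss >= 0 and lb.obj_loss >= 0


def test_loss_near_zero_for_perfect_predictions():
    """Raw maps carrying the exact target geometry at every assigned
    anchor/cell pair, with saturated objectness, drive the loss to ~0."""
    anchors = AnchorSet()
    img = 128
    labels = np.array([[0, 2, 0.4, 0.5, 0.15, 0.2]])
    grids = [(img // s, img // s) for s in (8, 16, 32)]
    asg = assign_targets(labels, anchors, grids)
    logit = lambda p: np.log(p / (1 - p))
    raws = []
    for (gh, gw), a in zip(grids, asg):
        raw = np.full((1, 3, 12, gh, gw), -12.0, dtype=np.float32)
        for m in range(len(a)):
            sxy = (a.txy[m] - [a.gi[m], a.gj[m]] + 0.5) / 2.0
            swh = np.sqrt(a.twh[m] / a.anchor_wh[m]) / 2.0
            raw[0, a.anchor[m], 0:2, a.gj[m], a.gi[m]] = logit(sxy)
            raw[0, a.anchor[m], 2:4, a.gj[m], a.gi[m]] = logit(swh)
            raw[0, a.anchor[m], 4, a.gj[m], a.gi[m]] = 12.0
            raw[0, a.anchor[m], 5 + a.cls[m], a.gj[m], a.gi[m]] = 12.0
        raws.append(Tensor(raw.reshape(1, 36, gh, gw)))
    lb = detection_loss(raws, labels, anchors, 7)
    assert lb.box_loss < 1e-3
    assert lb.cls_loss < 1e-3
    assert lb.total_value < 0.05


def test_loss_component_sum_hand_built():
    """One image, one label: total equals hand-summed components computed
    from the raw arrays outside the loss implementation."""
    rng = np.random.default_rng(9)
    anchors = AnchorSet()
    img = 64
    raws_np = [rng.normal(0, 0.5, (1, 36, img // s, img // s)).astype(np.float32)
               for s in (8, 16, 32)]
    labels = np.array([[0, 1, 0.5 + 0.01, 0.5 + 0.01, 60 / 640, 60 / 640]])
    lb = detection_loss([Tensor(r) for r in raws_np], labels, anchors, 7)

    # independent recomputation
    from yolocf.loss import assign_targets as at
    sig = lambda z: 1 / (1 + np.exp(-z.astype(np.float64)))
    grids = [(img // s, img // s) for s in (8, 16, 32)]
    asg = at(labels, anchors, grids)
    box_terms, cls_terms, obj_total, npairs = [], [], 0.0, 0
    for raw, a, bal in zip(raws_np, asg, (4.0, 1.0, 0.4)):
        H = raw.shape[2]
        pred = raw.reshape(1, 3, 12, H, H).transpose(0, 1, 3, 4, 2)
        tobj = np.zeros((1, 3, H, H))
        for m in range(len(a)):
            ps = pred[a.image[m], a.anchor[m], a.gj[m], a.gi[m]]
            s = sig(ps)
            pxy = s[0:2] * 2 - 0.5 + [a.gi[m], a.gj[m]]
            pwh = (s[2:4] * 2) ** 2 * a.anchor_wh[m]
            l = ciou_loss(np.concatenate([pxy, pwh]),
                          np.concatenate([a.txy[m], a.twh[m]]))
            iou = 1 - l  # only valid when penalties ~0; recompute properly:
            from yolocf.loss import ciou_terms
            _, iou_t = ciou_terms(Tensor(np.concatenate([pxy, pwh])[None]),
                                  Tensor(np.concatenate([a.txy[m], a.twh[m]])[None].astype(np.float32)))
            box_terms.append(l)
            tobj[a.image[m], a.anchor[m], a.gj[m], a.gi[m]] = max(
                tobj[a.image[m], a.anchor[m], a.gj[m], a.gi[m]],
                max(float(iou_t.data[0]), 0.0))
            y = np.zeros(7)
            y[a.cls[m]] = 1
            cls_terms.append(-np.mean(y * np.log(sig(ps[5:]))
                                      + (1 - y) * np.log(1 - sig(ps[5:]))))
            npairs += 1
        p_obj = sig(pred[..., 4])
        obj_total += bal * float(-np.mean(tobj * np.log(p_obj)
                                          + (1 - tobj) * np.log(1 - p_obj)))
    assert lb.box_loss == pytest.approx(np.mean(box_terms), rel=1e-3)
    assert lb.cls_loss == pytest.approx(np.mean(cls_terms), rel=1e-3)
    assert lb.obj_loss == pytest.approx(obj_total, rel=1e-3)
    assert lb.total_value == pytest.approx(
        0.05 * np.mean(box_terms) + obj_total + 0.5 * np.mean(cls_terms),
        rel=1e-3)
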