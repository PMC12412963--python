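"""Decode/NMS/letterbox/timing contracts, with brute-force NMS oracle."""

import numpy as np
import pytest

import oracles
from yolocf.loss import BoxXYWHN
from yolocf.model import AnchorSet
from yolocf.postprocess import (Detection, TimingReport, box_iou_xyxy,
                                decode, detections_to_jsonl,
                                detections_to_yolo_txt, encode_targets,
                                letterbox, nms, unletterbox_boxes)


@pytest.fixture(scope="module")
def anchors():
    return AnchorSet()


def det(x1, y1, x2, y2, cls=0, score=0.5):
    return Detection(BoxXYWHN((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1),
                     cls, score)


# -- decode -----------------------------------------------------------------

def test_decode_all_negative_objectness_empty(anchors):
    raws = [np.full((1, 36, 64 // s, 64 // s), -30.0, dtype=np.float32)
            for s in (8, 16, 32)]
    assert decode(raws, anchors, 0.25, 64) == [[]]


def test_decode_zero_threshold_counts(anchors):
    raws = [np.zeros((1, 36, 64 // s, 64 // s), dtype=np.float32)
            for s in (8, 16, 32)]
    dets = decode(raws, anchors, 0.0, 64)[0]
    assert len(dets) == 3 * (8 * 8 + 4 * 4 + 2 * 2)


def test_decode_scale_mismatch_raises(anchors):
    raws = [np.zeros((1, 36, 8, 8), dtype=np.float32)] * 2
    with pytest.raises(ValueError):
        decode(raws, anchors, 0.1, 64)


@pytest.mark.parametrize("trial", range(5))
def test_decode_encode_roundtrip(trial, anchors):
    """Boxes -> logits -> boxes recovers coordinates to high precision."""
    rng = np.random.default_rng(300 + trial)
    boxes = np.stack([rng.uniform(0.25, 0.75, 3), rng.uniform(0.25, 0.75, 3),
                      rng.uniform(0.05, 0.35, 3), rng.uniform(0.05, 0.35, 3)],
                     axis=1)
    cls = rng.integers(0, 7, 3)
    raws = encode_targets(boxes, cls, anchors, 320, 7)
    dets = decode(raws, anchors, 0.5, 320)[0]
    assert len(dets) == 3
    got = sorted([(d.box.cx, d.box.cy, d.box.w, d.box.h) for d in dets])
    want = sorted(map(tuple, boxes))
    assert np.abs(np.array(got) - np.array(want)).max() < 1e-5


# -- NMS --------------------------------------------------------------------

def test_nms_worked_example():
    a = det(0.1, 0.1, 0.5, 0.5, score=0.9)
    b = det(0.12, 0.12, 0.52, 0.52, score=0.7)  # IoU ~0.8 with a
    c = det(0.7, 0.7, 0.9, 0.9, score=0.6)
    kept = nms([a, b, c], 0.5)
    assert kept == [a, c]


def test_nms_disjoint_preserved():
    ds = [det(0.1 * i, 0.1 * i, 0.1 * i + 0.05, 0.1 * i + 0.05, score=0.3 + 0.05 * i)
          for i in range(5)]
    assert sorted(nms(ds, 0.5), key=lambda d: d.score) == ds


def test_nms_duplicate_boxes_single_survivor():
    d1 = det(0.2, 0.2, 0.4, 0.4, score=0.8)
    d2 = det(0.2, 0.2, 0.4, 0.4, score=0.8)
    assert len(nms([d1, d2], 0.5)) == 1


def test_nms_class_aware():
    d1 = det(0.2, 0.2, 0.4, 0.4, cls=0, score=0.9)
    d2 = det(0.2, 0.2, 0.4, 0.4, cls=1, score=0.8)
    assert len(nms([d1, d2], 0.5)) == 2


@pytest.mark.parametrize("trial", range(25))
def test_nms_equals_bruteforce(trial):
    rng = np.random.default_rng(400 + trial)
    n = int(rng.integers(1, 11))
    xy = rng.uniform(0, 0.7, (n, 2))
    wh = rng.uniform(0.05, 0.3, (n, 2))
    boxes = np.concatenate([xy, xy + wh], axis=1)
    scores = rng.uniform(0.1, 1.0, n).round(2)  # rounded -> real ties
    classes = rng.integers(0, 3, n)
    dets = [det(*boxes[i], cls=int(classes[i]), score=float(scores[i]))
            for i in range(n)]
    kept = nms(dets, 0.5)
    want_idx = oracles.nms_bruteforce(boxes, scores, classes, 0.5)
    want = [dets[i] for i in want_idx]
    assert sorted(kept, key=lambda d: (-d.score, d.class_id, d.box.cx)) \
        == sorted(want, key=lambda d: (-d.score, d.class_id, d.box.cx))


def test_nms_postcondition_no_overlapping_survivors(rng):
    for _ in range(20):
        n = int(rng.integers(2, 10))
        xy = rng.uniform(0, 0.6, (n, 2))
        wh = rng.uniform(0.1, 0.4, (n, 2))
        dets = [det(*xy[i], *(xy[i] + wh[i]), cls=int(rng.integers(0, 2)),
                    score=float(rng.uniform(0, 1))) for i in range(n)]
        kept = nms(dets, 0.45)
        assert all(d in dets for d in kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if a.class_id == b.class_id:
                    iou = box_iou_xyxy(np.array(a.xyxy()),
                                       np.array(b.xyxy()))[0, 0]
                    assert iou <= 0.45 + 1e-9


# -- letterbox --------------------------------------------------------------

def test_letterbox_shapes_and_inverse():
    img = np.arange(60 * 100 * 3, dtype=np.uint8).reshape(60, 100, 3)
    out, r, (dw, dh) = letterbox(img, 64)
    assert out.shape == (64, 64, 3)
    assert r == pytest.approx(0.64)
    boxes = np.array([[10.0, 5.0, 50.0, 30.0]])
    fwd = boxes * r
    fwd[:, [0, 2]] += dw
    fwd[:, [1, 3]] += dh
    back = unletterbox_boxes(fwd, r, (dw, dh), (60, 100))
    assert np.allclose(back, boxes, atol=1e-6)


# -- timing -----------------------------------------------------------------

def test_timing_eq_identity():
    rep = TimingReport(1.0, 2.0, 1.0)
    assert rep.fps == pytest.approx(250.0)
    rep2 = TimingReport(0.2, 2.1, 0.8)
    assert rep2.fps == pytest.approx(1000.0 / (0.2 + 2.1 + 0.8))


def test_time_inference_runs(tiny_model):
    img = np.zeros((96, 96, 3), dtype=np.uint8)
    rep = __import__("yolocf.postprocess", fromlist=["time_inference"]) \
        .time_inference(tiny_model, img, repeats=1, warmup=0)
    assert rep.t_infer > 0 and rep.fps > 0


# -- writers ----------------------------------------------------------------

def test_detection_writers(tmp_path):
    ds = [det(0.1, 0.1, 0.3, 0.3, cls=2, score=0.75)]
    txt = detections_to_yolo_txt(ds, tmp_path / "d.txt")
    parts = txt.split()
    assert parts[0] == "2" and len(parts) == 6
    jl = detections_to_jsonl(ds)
    import json
    rec = json.loads(jl)
    assert rec["class_id"] == 2 and rec["score"] == pytest.approx(0.75)
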