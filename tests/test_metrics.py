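"""Detection metrics and count analysis: worked values, laws, and the
curve-integration oracle."""

import numpy as np
import pytest

import oracles
from yolocf.loss import BoxXYWHN
from yolocf.metrics import (average_precision, count_analysis,
                            counts_from_detections, evaluate_detections,
                            map50, match_detections)
from yolocf.postprocess import Detection


def det(cx, cy, w, h, cls=0, score=0.9):
    return Detection(BoxXYWHN(cx, cy, w, h), cls, score)


GT = np.array([[0, 0.3, 0.3, 0.2, 0.2], [1, 0.7, 0.7, 0.2, 0.2]])


def test_perfect_detections():
    preds = [det(0.3, 0.3, 0.2, 0.2, 0), det(0.7, 0.7, 0.2, 0.2, 1)]
    res = evaluate_detections([preds], [GT], 2)
    assert res.map50 == pytest.approx(1.0)
    assert res.fp.sum() == 0 and res.fn.sum() == 0
    assert np.allclose(res.precision, 1) and np.allclose(res.recall, 1)


def test_zero_detections():
    res = evaluate_detections([[]], [GT], 2)
    assert res.map50 == 0.0
    assert np.allclose(res.precision, 0) and np.allclose(res.recall, 0)


def test_class_confusion_is_fp():
    preds = [det(0.3, 0.3, 0.2, 0.2, cls=1)]  # right box, wrong class
    tp, _, _, _ = match_detections(preds, GT)
    assert not tp.any()


def test_one_to_one_matching():
    # two detections on one truth: only the higher-scoring one matches
    preds = [det(0.3, 0.3, 0.2, 0.2, 0, 0.9), det(0.3, 0.3, 0.2, 0.2, 0, 0.8)]
    tp, _, _, _ = match_detections(preds, GT)
    assert tp.tolist() == [True, False]


def test_ap_single_truth_top_ranked():
    assert average_precision([True], [0.9], 1) == pytest.approx(1.0)


def test_ap_fp_above_tp_101point():
    """One FP ranked above one TP, one truth: all-point AP would be 0.5;
    the 101-point value comes from the independent curve oracle."""
    got = average_precision([False, True], [0.9, 0.8], 1)
    want = oracles.ap_bruteforce([False, True], [0.9, 0.8], 1)
    assert got == pytest.approx(want, abs=1e-9)
    assert got == pytest.approx(0.5, abs=0.01)


@pytest.mark.parametrize("trial", range(15))
def test_ap_matches_curve_oracle(trial):
    rng = np.random.default_rng(500 + trial)
    n = int(rng.integers(1, 20))
    tp = rng.random(n) < 0.5
    scores = rng.random(n).round(2)
    n_truth = int(tp.sum() + rng.integers(0, 5)) or 1
    assert average_precision(tp, scores, n_truth) == pytest.approx(
        oracles.ap_bruteforce(tp, scores, n_truth), abs=1e-9)


def test_ap_monotone_under_added_fp(rng):
    for _ in range(20):
        n = int(rng.integers(1, 12))
        tp = (rng.random(n) < 0.6).tolist()
        scores = rng.random(n).tolist()
        base = average_precision(tp, scores, max(sum(tp), 1))
        worse = average_precision(tp + [False], scores + [float(rng.random())],
                                  max(sum(tp), 1))
        assert worse <= base + 1e-12


def test_map_simple_mean():
    assert map50([1.0, 0.0]) == pytest.approx(0.5)
    assert map50([1.0, float("nan")]) == pytest.approx(1.0)  # no-truth class excluded


def test_self_evaluation_map_is_one(rng):
    """A detector evaluated against its own outputs as truth scores 1."""
    preds, gts = [], []
    for _ in range(5):
        n = int(rng.integers(1, 6))
        dets = [det(*rng.uniform(0.2, 0.8, 2), *rng.uniform(0.05, 0.2, 2),
                    cls=int(rng.integers(0, 3)), score=float(rng.uniform(0.3, 1)))
                for _ in range(n)]
        preds.append(dets)
        gts.append(np.array([[d.class_id, d.box.cx, d.box.cy, d.box.w, d.box.h]
                             for d in dets]))
    assert evaluate_detections(preds, gts, 3).map50 == pytest.approx(1.0)


# -- count analysis ---------------------------------------------------------

def test_count_exact_agreement():
    rep = count_analysis([3, 5, 2], [3, 5, 2])
    assert rep.mae == 0 and rep.rmse == 0 and rep.r2 == pytest.approx(1.0)


def test_count_worked_example():
    """y=[3,5,2], yhat=[2,5,4]: MAE=1, RMSE=sqrt(5/3), R2=1-5/(14/3)."""
    rep = count_analysis([3, 5, 2], [2, 5, 4])
    assert rep.mae == pytest.approx(1.0)
    assert rep.rmse == pytest.approx(np.sqrt(5 / 3))
    assert rep.r2 == pytest.approx(1 - 5 / (14 / 3))
    assert rep.r2 < 0  # worse than predicting the mean


def test_count_constant_prediction_r2_zero():
    y = [1, 2, 3, 4, 5]
    rep = count_analysis(y, [3, 3, 3, 3, 3])
    assert rep.r2 == pytest.approx(0.0)


def test_count_errors():
    with pytest.raises(ValueError):
        count_analysis([2, 2, 2], [1, 2, 3])  # constant truths
    with pytest.raises(ValueError):
        count_analysis([1], [1])
    with pytest.raises(ValueError):
        count_analysis([1, 2], [1, -2])


def test_mae_le_rmse_on_random_vectors(rng):
    for _ in range(1000):
        n = int(rng.integers(2, 30))
        y = rng.integers(0, 20, n)
        if y.min() == y.max():
            continue
        yh = rng.integers(0, 20, n)
        rep = count_analysis(y, yh)
        assert rep.mae <= rep.rmse + 1e-12
        assert rep.r2 <= 1.0
        # residuals all zero iff R2 == 1
        assert (rep.r2 == pytest.approx(1.0)) == bool((y == yh).all())


def test_r2_invariant_to_joint_permutation(rng):
    y = rng.integers(0, 15, 40)
    yh = rng.integers(0, 15, 40)
    if y.min() == y.max():
        y[0] += 1
    perm = rng.permutation(40)
    a = count_analysis(y, yh)
    b = count_analysis(y[perm], yh[perm])
    assert a.r2 == pytest.approx(b.r2)
    assert a.mae == pytest.approx(b.mae)


def test_counts_from_detections_pooled_and_per_class():
    imgs = [[det(0.3, 0.3, 0.1, 0.1, cls=0), det(0.6, 0.6, 0.1, 0.1, cls=1)],
            [det(0.5, 0.5, 0.1, 0.1, cls=1)]]
    assert counts_from_detections(imgs).tolist() == [2, 1]
    mat = counts_from_detections(imgs, per_class=True, num_classes=2)
    assert mat.tolist() == [[1, 1], [0, 1]]


def test_per_class_csv_table():
    preds = [det(0.3, 0.3, 0.2, 0.2, 0)]
    res = evaluate_detections([preds], [GT], 2)
    table = res.per_class_table(["apple", "pear"])
    assert "apple" in table and "mAP50" in table
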