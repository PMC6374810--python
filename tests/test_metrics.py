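"""Evaluation metrics against hand counts and brute-force oracles."""

import numpy as np
import pytest

from msdseg.metrics import (SegmentationPair, aggregate, asd, boundary_voxels,
                            confusion_counts, dsc, evaluate_pair, recall)
from msdseg.volio import LabelMask, VolumeImage, rotate_sagittal


def brute_force_confusion(pred, truth):
    tp = fp = fn = tn = 0
    for idx in np.ndindex(pred.shape):
        p, t = bool(pred[idx]), bool(truth[idx])
        tp += p and t
        fp += p and not t
        fn += t and not p
        tn += not p and not t
    return tp, fp, fn, tn


def brute_force_asd(pred, truth, spacing):
    bp = np.argwhere(boundary_voxels(pred)) * np.asarray(spacing)
    bg = np.argwhere(boundary_voxels(truth)) * np.asarray(spacing)
    total = 0.0
    for p in bp:
        total += min(np.sqrt(((p - q) ** 2).sum()) for q in bg)
    for q in bg:
        total += min(np.sqrt(((q - p) ** 2).sum()) for p in bp)
    return total / (len(bp) + len(bg))


def test_confusion_counts_examples_and_oracle(rng):
    a = np.zeros((4, 4, 4), bool)
    a[1:3, 1:3, 1:3] = True
    same = SegmentationPair(a, a)
    tp, fp, fn, tn = confusion_counts(same)
    assert fp == 0 and fn == 0 and tp == 8 and tp + tn == a.size
    comp = SegmentationPair(~a, a)
    tp, fp, fn, tn = confusion_counts(comp)
    assert tp == 0 and tn == 0
    for _ in range(10):
        p = rng.random((8, 8, 8)) > 0.5
        t = rng.random((8, 8, 8)) > 0.5
        assert confusion_counts(SegmentationPair(p, t)) == brute_force_confusion(p, t)


def test_dsc_hand_counts():
    p = np.zeros((4, 4, 1), bool)
    t = np.zeros((4, 4, 1), bool)
    p[0, 0] = p[0, 1] = True          # |Sp| = 2
    t[0, 1] = t[1, 1] = t[2, 2] = True  # |Sg| = 3, overlap 1
    assert dsc(SegmentationPair(p, t)) == pytest.approx(0.4)
    assert dsc(SegmentationPair(t, t)) == 1.0
    q = np.zeros_like(p)
    q[3, 3] = True
    assert dsc(SegmentationPair(q, t)) == 0.0
    empty = np.zeros_like(p)
    assert dsc(SegmentationPair(empty, empty)) == 1.0


def test_dsc_symmetry_recall_asymmetry(rng):
    p = rng.random((6, 6, 6)) > 0.6
    t = rng.random((6, 6, 6)) > 0.6
    assert dsc(SegmentationPair(p, t)) == pytest.approx(dsc(SegmentationPair(t, p)))
    r1 = recall(SegmentationPair(p, t))
    r2 = recall(SegmentationPair(t, p))
    assert r1 != pytest.approx(r2)  # generically asymmetric


def test_recall_examples_and_empty_truth_error():
    t = np.zeros((3, 3, 3), bool)
    t[0, 0, 0] = t[1, 1, 1] = t[2, 2, 2] = True
    sup = np.ones_like(t)
    assert recall(SegmentationPair(sup, t)) == 1.0
    p = np.zeros_like(t)
    assert recall(SegmentationPair(p, t)) == 0.0
    p[0, 0, 0] = True  # TP=1, FN=2
    assert recall(SegmentationPair(p, t)) == pytest.approx(1 / 3)
    with pytest.raises(ValueError, match="empty"):
        recall(SegmentationPair(p, np.zeros_like(t)))


def test_dsc_monotone_in_correct_voxels(rng):
    t = rng.random((6, 6, 6)) > 0.5
    p = t & (rng.random((6, 6, 6)) > 0.5)
    base = dsc(SegmentationPair(p, t))
    missing = np.argwhere(t & ~p)
    p2 = p.copy()
    p2[tuple(missing[0])] = True
    assert dsc(SegmentationPair(p2, t)) >= base


def test_boundary_voxels_hand_cases():
    single = np.zeros((5, 5, 5), bool)
    single[2, 2, 2] = True
    np.testing.assert_array_equal(boundary_voxels(single), single)
    cube = np.zeros((5, 5, 5), bool)
    cube[1:4, 1:4, 1:4] = True
    b = boundary_voxels(cube)
    assert b.sum() == 26 and not b[2, 2, 2]
    # volume border counts as background
    full = np.ones((3, 3, 3), bool)
    assert boundary_voxels(full).sum() == 26  # all but the center
    # idempotent on thin sets
    np.testing.assert_array_equal(boundary_voxels(b), b)
    with pytest.raises(ValueError):
        boundary_voxels(np.zeros((3, 3, 3), bool))


def test_asd_hand_count_and_identity():
    a = np.zeros((8, 8, 8), bool)
    b = np.zeros((8, 8, 8), bool)
    a[1, 1, 1] = True
    b[1, 1, 6] = True  # 5 voxels apart along one axis
    assert asd(SegmentationPair(a, b, (1, 1, 1))) == pytest.approx(5.0)
    assert asd(SegmentationPair(a, a, (1, 1, 1))) == 0.0
    with pytest.raises(ValueError):
        asd(SegmentationPair(a, np.zeros_like(b), (1, 1, 1)))


def test_asd_spacing_aware():
    a = np.zeros((4, 4, 8), bool)
    b = np.zeros((4, 4, 8), bool)
    a[1, 1, 1] = True
    b[1, 1, 5] = True
    assert asd(SegmentationPair(a, b, (1, 1, 1.2))) == pytest.approx(4 * 1.2)


def test_asd_matches_brute_force_oracle(rng):
    for _ in range(10):
        p = rng.random((8, 8, 8)) > 0.7
        t = rng.random((8, 8, 8)) > 0.7
        if not p.any() or not t.any():
            continue
        pair = SegmentationPair(p, t, (0.6, 0.6, 1.2))
        assert asd(pair) == pytest.approx(
            brute_force_asd(p, t, (0.6, 0.6, 1.2)), abs=1e-9)


def test_dsc_recall_invariant_under_joint_rotation(rng):
    p = rng.random((6, 6, 4)) > 0.6
    t = rng.random((6, 6, 4)) > 0.6
    t[0, 0, 0] = True
    sp = (0.6, 0.6, 1.2)
    pv, pm = rotate_sagittal(VolumeImage(p.astype(np.float32), sp),
                             LabelMask(p.astype(np.uint8), sp), 90)
    tv, tm = rotate_sagittal(VolumeImage(t.astype(np.float32), sp),
                             LabelMask(t.astype(np.uint8), sp), 90)
    before = SegmentationPair(p, t, sp)
    after = SegmentationPair(pm.data, tm.data, pm.spacing)
    assert dsc(after) == pytest.approx(dsc(before))
    assert recall(after) == pytest.approx(recall(before))


def test_aggregate_mean_sd_and_order_invariance():
    reports = [{"DSC": 0.8, "RR": 0.7, "ASD_mm": 2.0},
               {"DSC": 0.9, "RR": 0.9, "ASD_mm": 1.0}]
    t1 = aggregate(reports)
    mean_row = t1[t1["case"] == "mean"].iloc[0]
    assert mean_row["DSC"] == pytest.approx(0.85)
    sd_row = t1[t1["case"] == "sd"].iloc[0]
    assert sd_row["DSC"] == pytest.approx(np.std([0.8, 0.9], ddof=1))
    t2 = aggregate(reports[::-1])
    assert t2[t2["case"] == "mean"]["DSC"].iloc[0] == pytest.approx(0.85)
    single = aggregate(reports[:1])
    assert single[single["case"] == "sd"]["DSC"].iloc[0] == 0.0


def test_evaluate_pair_reports_all_three_metrics(rng):
    t = np.zeros((6, 6, 6), bool)
    t[2:5, 2:5, 2:5] = True
    p = np.zeros_like(t)
    p[2:5, 2:4, 2:5] = True
    rep = evaluate_pair(SegmentationPair(p, t, (1, 1, 1)))
    assert set(rep) == {"DSC", "RR", "ASD_mm"}
    assert 0 < rep["DSC"] < 1 and 0 < rep["RR"] < 1 and rep["ASD_mm"] > 0
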