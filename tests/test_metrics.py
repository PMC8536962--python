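"""Metric suite against brute-force oracles and hand-computed values."""

import numpy as np
import pytest

from simounet.metrics import (
    agreement,
    brain_volume_cm3,
    confusion_counts,
    evaluate_case,
    hausdorff_mm,
    overlap_metrics,
)


def random_mask(rng, shape=(8, 8), p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)


# -- confusion / overlap -------------------------------------------------


def test_confusion_perfect_and_complement():
    ones = np.ones((4, 4), dtype=np.uint8)
    assert confusion_counts(ones, ones) == (16, 0, 0, 0)
    zeros = np.zeros((4, 4), dtype=np.uint8)
    tp, fp, fn, tn = confusion_counts(zeros, ones)
    assert (tp, tn) == (0, 0) and (fp, fn) == (0, 16)


def test_confusion_matches_pixel_loop(rng):
    for _ in range(20):
        a, b = random_mask(rng), random_mask(rng)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                if a[i, j] and b[i, j]:
                    tp += 1
                elif a[i, j]:
                    fp += 1
                elif b[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert confusion_counts(a, b) == (tp, fp, fn, tn)


def test_overlap_formulas():
    assert overlap_metrics(10, 0, 0) == (1.0, 1.0, 1.0)
    j, d, sen = overlap_metrics(1, 1, 1)
    assert (j, d, sen) == (pytest.approx(1 / 3), pytest.approx(0.5), pytest.approx(0.5))


def test_dice_jaccard_identity(rng):
    for _ in range(50):
        tp, fp, fn = rng.integers(0, 40, 3)
        j, d, _ = overlap_metrics(int(tp) + 1, int(fp), int(fn))
        assert d == pytest.approx(2 * j / (1 + j))
        assert j <= d


def test_empty_union_flags_missing():
    j, d, sen = overlap_metrics(0, 0, 0)
    assert j is None and d is None and sen is None


# -- hausdorff -----------------------------------------------------------


def _hausdorff_bruteforce(a, b, spacing):
    dy, dx = spacing[1], spacing[0]
    pa = [(i * dy, j * dx) for i, j in zip(*np.nonzero(a))]
    pb = [(i * dy, j * dx) for i, j in zip(*np.nonzero(b))]
    def directed(ps, qs):
        return max(min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in qs) for p in ps)
    return max(directed(pa, pb), directed(pb, pa))


def test_hausdorff_identical_masks_zero(rng):
    m = random_mask(rng)
    m[0, 0] = 1
    assert hausdorff_mm(m, m, (1.0, 1.0)) == 0.0


def test_hausdorff_pythagoras():
    a = np.zeros((8, 8), dtype=np.uint8)
    b = np.zeros((8, 8), dtype=np.uint8)
    a[0, 0] = 1
    b[3, 4] = 1
    assert hausdorff_mm(a, b, (1.0, 1.0)) == pytest.approx(5.0)


def test_hausdorff_matches_all_pairs_oracle(rng):
    for _ in range(15):
        a, b = random_mask(rng, p=0.2), random_mask(rng, p=0.2)
        if not a.any() or not b.any():
            continue
        got = hausdorff_mm(a, b, (0.8, 1.3))
        assert got == pytest.approx(_hausdorff_bruteforce(a, b, (0.8, 1.3)), abs=1e-9)


def test_hausdorff_symmetric_and_scales_with_spacing(rng):
    a, b = random_mask(rng, p=0.3), random_mask(rng, p=0.3)
    a[2, 2] = b[5, 5] = 1
    assert hausdorff_mm(a, b, (1.0, 1.0)) == hausdorff_mm(b, a, (1.0, 1.0))
    assert hausdorff_mm(a, b, (2.5, 2.5)) == pytest.approx(
        2.5 * hausdorff_mm(a, b, (1.0, 1.0))
    )


def test_hausdorff_empty_mask_flagged():
    a = np.zeros((4, 4), dtype=np.uint8)
    b = np.ones((4, 4), dtype=np.uint8)
    assert hausdorff_mm(a, b, (1.0, 1.0)) is None


# -- volume --------------------------------------------------------------


def test_volume_unit_cube():
    stack = np.ones((5, 10, 10), dtype=np.uint8)
    assert brain_volume_cm3(stack, (1.0, 1.0), 2.0) == pytest.approx(1.0)


def test_volume_empty_stack():
    assert brain_volume_cm3(np.zeros((3, 4, 4), dtype=np.uint8), (1.0, 1.0), 1.0) == 0.0


def test_volume_matches_voxel_count_oracle(rng):
    stack = (rng.random((4, 8, 8)) > 0.5).astype(np.uint8)
    dx, dy, dz = 0.7, 1.1, 2.6
    assert brain_volume_cm3(stack, (dx, dy), dz) == pytest.approx(
        stack.sum() * dx * dy * dz / 1000.0
    )


def test_volume_additive_over_slice_subsets(rng):
    stack = (rng.random((6, 8, 8)) > 0.4).astype(np.uint8)
    total = brain_volume_cm3(stack, (1.0, 1.0), 2.0)
    parts = brain_volume_cm3(stack[:3], (1.0, 1.0), 2.0) + brain_volume_cm3(
        stack[3:], (1.0, 1.0), 2.0
    )
    assert total == pytest.approx(parts)


def test_non_binary_stack_rejected(rng):
    with pytest.raises(ValueError):
        brain_volume_cm3(rng.random((2, 4, 4)), (1.0, 1.0), 1.0)


# -- per-case evaluation -------------------------------------------------


def _toy_case(rng, s=4, size=12):
    truth = np.zeros((s, size, size), dtype=np.uint8)
    for i in range(s):
        truth[i, 3:9, 3:9] = 1
    return truth


def test_evaluate_case_perfect_prediction(rng):
    truth = _toy_case(rng)
    cm = evaluate_case(truth.astype(float), truth, (1.0, 1.0), 2.0)
    assert cm.jaccard == cm.dice == cm.sensitivity == 1.0
    assert cm.hausdorff_mm == 0.0 and cm.mavd_cm3 == 0.0


def test_evaluate_case_missing_slice_volume_arithmetic():
    truth = _toy_case(None)
    pred = truth.astype(float).copy()
    pred[1] = 0.0  # one slice entirely missed
    dx, dy, dz = 0.9, 1.1, 2.0
    cm = evaluate_case(pred, truth, (dx, dy), dz)
    assert cm.volume_auto_cm3 < cm.volume_manual_cm3
    assert cm.mavd_cm3 == pytest.approx(truth[1].sum() * dx * dy * dz / 1000.0)


def test_evaluate_case_dice_is_mean_of_slice_dices(rng):
    truth = _toy_case(rng)
    pred = np.clip(truth + rng.normal(0, 0.4, truth.shape), 0, 1)
    cm = evaluate_case(pred, truth, (1.0, 1.0), 2.0)
    per_slice = []
    for s in range(truth.shape[0]):
        p = (pred[s] >= 0.5).astype(np.uint8)
        tp, fp, fn, _ = confusion_counts(p, truth[s])
        per_slice.append(2 * tp / (2 * tp + fp + fn))
    assert cm.dice == pytest.approx(np.mean(per_slice))


def test_evaluate_case_empty_truth_slices_excluded_from_overlap():
    truth = _toy_case(None)
    truth[0] = 0  # empty ground-truth slice
    pred = truth.astype(float)
    cm = evaluate_case(pred, truth, (1.0, 1.0), 2.0)
    assert cm.n_slices_evaluated == 3
    assert cm.dice == 1.0


def test_evaluate_case_all_empty_truth_returns_none():
    truth = np.zeros((3, 6, 6), dtype=np.uint8)
    assert evaluate_case(truth.astype(float), truth, (1.0, 1.0), 2.0) is None


# -- agreement -----------------------------------------------------------


def test_agreement_perfect():
    v = [10.0, 20.0, 30.0]
    rep = agreement(v, v)
    assert rep.r_squared == pytest.approx(1.0)
    assert rep.mean_diff_cm3 == 0.0
    assert rep.loa_low_cm3 == rep.loa_high_cm3 == 0.0


def test_agreement_hand_computed_differences():
    manual = np.array([10.0, 20.0, 30.0])
    auto = manual + np.array([1.0, 2.0, 3.0])
    rep = agreement(auto, manual)
    assert rep.mean_diff_cm3 == pytest.approx(2.0)
    assert rep.loa_low_cm3 == pytest.approx(2.0 - 1.96)
    assert rep.loa_high_cm3 == pytest.approx(2.0 + 1.96)
    assert rep.n_cases == 3


def test_agreement_scaled_volumes_keep_perfect_correlation():
    manual = np.array([5.0, 10.0, 20.0, 40.0])
    rep = agreement(2 * manual, manual)
    assert rep.r_squared == pytest.approx(1.0)
    assert rep.mean_diff_cm3 != 0.0


def test_agreement_zero_variance_flagged():
    rep = agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(rep.r_squared)


def test_agreement_loa_bracket_mean(rng):
    auto = rng.random(10) * 50
    manual = rng.random(10) * 50
    rep = agreement(auto, manual)
    assert rep.loa_low_cm3 <= rep.mean_diff_cm3 <= rep.loa_high_cm3
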