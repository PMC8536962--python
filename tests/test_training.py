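"""Hybrid loss closed forms and invariants, fold planning, early
stopping, and a miniature optimisation smoke."""

import math

import numpy as np
import pandas as pd
import pytest

from simounet.architecture import HEAD_ORDER, build_simou_spec, instantiate
from simounet.training import (
    EarlyStopper,
    TrainingConfig,
    hybrid_loss,
    stratified_group_folds,
    total_objective,
    train,
)


# -- hybrid loss ---------------------------------------------------------


def test_perfect_foreground_prediction_gives_minus_one():
    y = np.ones((6, 6))
    assert hybrid_loss(y, y) == pytest.approx(-1.0, abs=1e-6)


def test_perfect_background_prediction_gives_minus_one():
    z = np.zeros((6, 6))
    assert hybrid_loss(z, z) == pytest.approx(-1.0, abs=1e-6)


def test_half_probability_closed_form():
    y = np.ones((8, 8))
    pred = np.full((8, 8), 0.5)
    expected = -(0.5 * math.log(0.5) + 2.0 / 3.0)
    assert hybrid_loss(pred, y) == pytest.approx(expected, abs=1e-6)


def test_loss_minimal_at_truth(rng):
    y = (rng.random((10, 10)) > 0.6).astype(float)
    base = hybrid_loss(y, y)
    for _ in range(25):
        pred = np.clip(y + rng.normal(0, 0.2, y.shape), 0, 1)
        assert hybrid_loss(pred, y) >= base - 1e-9


def test_loss_permutation_invariant(rng):
    y = (rng.random((9, 9)) > 0.5).astype(float)
    pred = rng.random((9, 9))
    perm = rng.permutation(81)
    a = hybrid_loss(pred, y)
    b = hybrid_loss(pred.ravel()[perm].reshape(9, 9), y.ravel()[perm].reshape(9, 9))
    assert a == pytest.approx(b, rel=1e-6)


def test_loss_batch_is_mean_of_per_image_losses(rng):
    preds = rng.random((3, 7, 7))
    truths = (rng.random((3, 7, 7)) > 0.5).astype(float)
    batch = hybrid_loss(preds, truths)
    singles = [hybrid_loss(preds[i], truths[i]) for i in range(3)]
    assert batch == pytest.approx(np.mean(singles), rel=1e-5)


def test_non_binary_truth_rejected(rng):
    with pytest.raises(ValueError, match="binary"):
        hybrid_loss(rng.random((4, 4)), rng.random((4, 4)))


def test_shape_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        hybrid_loss(rng.random((4, 4)), np.ones((4, 5)))


# -- total objective -----------------------------------------------------


def _pred_dict(rng):
    return {h: rng.random((2, 6, 6)) for h in HEAD_ORDER}


def test_single_alpha_selects_one_head(rng):
    preds = _pred_dict(rng)
    y = (rng.random((2, 6, 6)) > 0.5).astype(float)
    assert total_objective(preds, y, (1, 0, 0, 0, 0)) == pytest.approx(
        hybrid_loss(preds["d_ux"], y), rel=1e-6
    )


def test_identical_heads_scale_linearly(rng):
    p = rng.random((2, 6, 6))
    preds = {h: p for h in HEAD_ORDER}
    y = (rng.random((2, 6, 6)) > 0.5).astype(float)
    assert total_objective(preds, y, (1,) * 5) == pytest.approx(
        5 * hybrid_loss(p, y), rel=1e-6
    )


def test_objective_linear_in_alpha(rng):
    preds = _pred_dict(rng)
    y = (rng.random((2, 6, 6)) > 0.5).astype(float)
    per_head = [hybrid_loss(preds[h], y) for h in HEAD_ORDER]
    alphas = (0.2, 0.2, 0.2, 0.2, 0.2)
    assert total_objective(preds, y, alphas) == pytest.approx(
        np.mean(per_head), rel=1e-6
    )
    a1 = np.array([0.5, 1.0, 0.0, 2.0, 0.3])
    a2 = np.array([1.0, 0.1, 0.2, 0.0, 1.0])
    lhs = total_objective(preds, y, tuple(a1 + a2))
    rhs = total_objective(preds, y, tuple(a1)) + total_objective(preds, y, tuple(a2))
    assert lhs == pytest.approx(rhs, rel=1e-6)


# -- fold planning -------------------------------------------------------


def _manifest(n, strata=None):
    return pd.DataFrame(
        {"subject_id": [f"S{i:03d}" for i in range(n)],
         "stratum": strata if strata is not None else ["all"] * n}
    )


def test_six_subjects_three_folds_single_stratum():
    plan = stratified_group_folds(_manifest(6), k=3, seed=0)
    sizes = [len(plan.fold_subjects(f)) for f in range(3)]
    assert sizes == [2, 2, 2]


def test_folds_partition_subjects():
    plan = stratified_group_folds(_manifest(10), k=3, seed=1)
    all_ids = [s for f in range(3) for s in plan.fold_subjects(f)]
    assert sorted(all_ids) == sorted(plan.assignments)
    assert len(all_ids) == len(set(all_ids)) == 10


def test_four_strata_of_two_split_evenly_over_two_folds():
    strata = ["a", "a", "b", "b", "c", "c", "d", "d"]
    plan = stratified_group_folds(_manifest(8, strata), k=2, seed=3)
    for fold in range(2):
        members = plan.fold_subjects(fold)
        assert len(members) == 4
        assert sorted(plan.strata[s] for s in members) == ["a", "b", "c", "d"]


@pytest.mark.parametrize("n,k", [(6, 3), (9, 3), (14, 4), (24, 3)])
def test_within_stratum_balance(n, k, rng):
    strata = [f"q{rng.integers(0, 4)}" for _ in range(n)]
    plan = stratified_group_folds(_manifest(n, strata), k=k, seed=5)
    for st in set(strata):
        counts = [
            sum(1 for s in plan.fold_subjects(f) if plan.strata[s] == st)
            for f in range(k)
        ]
        assert max(counts) - min(counts) <= 1


def test_more_folds_than_subjects_rejected():
    with pytest.raises(ValueError):
        stratified_group_folds(_manifest(2), k=3, seed=0)


def test_fold_plan_deterministic():
    p1 = stratified_group_folds(_manifest(12), k=3, seed=7)
    p2 = stratified_group_folds(_manifest(12), k=3, seed=7)
    assert p1.assignments == p2.assignments


# -- early stopping ------------------------------------------------------


def test_early_stopper_stops_after_patience_without_improvement():
    stopper = EarlyStopper(patience=2)
    decisions = [stopper.update(v) for v in [1.0, 0.9, 0.95, 0.96]]
    assert decisions == [False, False, False, True]
    assert stopper.best_epoch == 2


def test_early_stopper_resets_on_improvement():
    stopper = EarlyStopper(patience=2)
    for v in [1.0, 0.9, 0.95, 0.85]:
        assert not stopper.update(v)
    assert stopper.best_epoch == 4


# -- training loop -------------------------------------------------------


def _micro_data(rng, n=16, size=16):
    yy, xx = np.mgrid[0:size, 0:size]
    images, masks = [], []
    for _ in range(n):
        cy, cx = rng.uniform(5, size - 5, 2)
        r = rng.uniform(2.0, 4.0)
        m = ((xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2)
        img = 0.2 + 0.6 * m + rng.normal(0, 0.05, (size, size))
        images.append(img)
        masks.append(m)
    return (np.array(images, dtype=np.float32),
            np.array(masks, dtype=np.float32))


def _micro_model(seed=0):
    spec = build_simou_spec((16, 16, 1), width_multiplier=1 / 16, n_levels=3,
                            dropout_rate=0.0)
    return instantiate(spec, seed=seed)


def test_training_reduces_loss(rng):
    images, masks = _micro_data(rng)
    cfg = TrainingConfig(seed=0, augmentation=False, batch_size=8,
                         max_epochs=4, early_stop_patience=3)
    history, info = train(_micro_model(), (images[:12], masks[:12]),
                          (images[12:], masks[12:]), cfg)
    assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]
    assert info["best_epoch"] >= 1


def test_training_deterministic_without_augmentation(rng):
    images, masks = _micro_data(rng)
    cfg = TrainingConfig(seed=3, augmentation=False, batch_size=8,
                         max_epochs=2, early_stop_patience=1)
    h1, _ = train(_micro_model(3), (images[:12], masks[:12]),
                  (images[12:], masks[12:]), cfg)
    h2, _ = train(_micro_model(3), (images[:12], masks[:12]),
                  (images[12:], masks[12:]), cfg)
    pd.testing.assert_frame_equal(h1, h2)


def test_training_with_augmentation_runs(rng):
    images, masks = _micro_data(rng, n=8)
    cfg = TrainingConfig(seed=1, augmentation=True, batch_size=8,
                         max_epochs=2, early_stop_patience=1)
    history, _ = train(_micro_model(1), (images[:6], masks[:6]),
                       (images[6:], masks[6:]), cfg)
    assert len(history) == 2
    assert np.isfinite(history["train_loss"]).all()


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(alpha_weights=(0, 0, 0, 0, 0)).validate()
    with pytest.raises(ValueError):
        TrainingConfig(early_stop_patience=1000, max_epochs=1000).validate()
    with pytest.raises(ValueError):
        TrainingConfig(alpha_weights=(1, 1, 1)).validate()
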