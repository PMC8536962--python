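"""End-to-end experiment drivers: train on a subject split, predict
the five maps plus fusions on held-out cases, and aggregate metrics.

These drivers implement the subject-grouped evaluation protocol: folds
are formed over whole subjects (stratified by mid-slice brain area
quartile), a validation subset of the training subjects steers early
stopping, and every held-out case is scored per prediction map and per
fusion operator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .architecture import (
    HEAD_ORDER,
    build_simou_spec,
    instantiate,
    predict,
)
from .fusion import fuse
from .metrics import agreement, evaluate_case
from .phantom import PhantomConfig, generate_dataset
from .training import TrainingConfig, stratified_group_folds, train

logger = logging.getLogger(__name__)

__all__ = ["stack_slices", "evaluate_maps", "run_fold", "run_crossval", "scaled_benchmark"]

#: map names scored on held-out cases: the five heads and three fusions
MAP_NAMES = tuple(HEAD_ORDER) + ("mean", "median", "max")


def stack_slices(stacks, subject_ids):
    """Concatenate the slices/masks of the listed subjects into
    (N, H, W) training arrays."""
    by_id = {s.subject_id: s for s in stacks}
    images = np.concatenate([by_id[i].slices for i in subject_ids])
    masks = np.concatenate([by_id[i].mask for i in subject_ids])
    return images.astype(np.float32), masks.astype(np.float32)


def evaluate_maps(model, stacks, subject_ids, threshold=0.5, batch_size=16):
    """Score each held-out case under every head and fusion operator.

    Returns {map_name: [CaseMetrics per subject]}.
    """
    by_id = {s.subject_id: s for s in stacks}
    results = {name: [] for name in MAP_NAMES}
    for sid in subject_ids:
        stack = by_id[sid]
        preds = predict(model, stack.slices, batch_size=batch_size)
        maps = {h: preds[h] for h in HEAD_ORDER}
        for op in ("mean", "median", "max"):
            maps[op] = fuse(preds, op).values
        for name, prob in maps.items():
            cm = evaluate_case(
                prob, stack.mask, stack.pixel_spacing_mm,
                stack.slice_thickness_mm, threshold, subject_id=sid,
            )
            if cm is not None:
                results[name].append(cm)
    return results


def _val_split(train_ids, rng, val_fraction=0.2):
    train_ids = list(train_ids)
    rng.shuffle(train_ids)
    n_val = max(1, int(round(val_fraction * len(train_ids))))
    return sorted(train_ids[n_val:]), sorted(train_ids[:n_val])


def run_fold(stacks, train_ids, test_ids, train_cfg: TrainingConfig,
             width_multiplier=0.125, n_levels=7, threshold=0.5,
             val_fraction=0.2, max_epochs=None):
    """Train one model on ``train_ids`` (a seeded subset becomes the
    early-stopping validation set) and score ``test_ids``."""
    rng = np.random.default_rng(int(train_cfg.seed))
    fit_ids, val_ids = _val_split(train_ids, rng, val_fraction)
    h, w = stacks[0].slices.shape[1:]
    spec = build_simou_spec((h, w, 1), width_multiplier=width_multiplier,
                            n_levels=n_levels)
    model = instantiate(spec, seed=train_cfg.seed)
    cfg = train_cfg
    if max_epochs is not None:
        cfg = TrainingConfig(**{**cfg.__dict__, "max_epochs": max_epochs,
                                "early_stop_patience": min(cfg.early_stop_patience,
                                                           max_epochs - 1)})
    history, info = train(model, stack_slices(stacks, fit_ids),
                          stack_slices(stacks, val_ids), cfg)
    results = evaluate_maps(model, stacks, test_ids, threshold,
                            batch_size=cfg.batch_size)
    return {"model": model, "history": history, "info": info,
            "results": results, "val_ids": val_ids}


def run_crossval(phantom_cfg: PhantomConfig, k=3, seed=0,
                 train_cfg: TrainingConfig | None = None,
                 width_multiplier=0.125, n_levels=7, threshold=0.5,
                 max_epochs=None, stacks=None, manifest=None):
    """Full stratified subject-grouped k-fold protocol.

    Generates the phantom cohort (unless ``stacks``/``manifest`` are
    supplied), trains one model per fold and scores its held-out
    subjects.  Returns a dict with the per-case table, a mean +/- sd
    summary per map, the fold plan and the volume-agreement report of
    the mean-fused predictions over all held-out cases.
    """
    if stacks is None:
        stacks, manifest = generate_dataset(phantom_cfg)
    if train_cfg is None:
        train_cfg = TrainingConfig(seed=seed, augmentation=False)
    plan = stratified_group_folds(manifest, k, seed)
    rows = []
    v_auto, v_manual = [], []
    fold_outputs = []
    for fold in range(k):
        train_ids, test_ids = plan.split(fold)
        cfg = TrainingConfig(**{**train_cfg.__dict__,
                                "seed": int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))})
        out = run_fold(stacks, train_ids, test_ids, cfg,
                       width_multiplier=width_multiplier, n_levels=n_levels,
                       threshold=threshold, max_epochs=max_epochs)
        fold_outputs.append(out)
        for name, cases in out["results"].items():
            for cm in cases:
                rows.append({"fold": fold, "map": name, "subject_id": cm.subject_id,
                             "jaccard": cm.jaccard, "dice": cm.dice,
                             "sensitivity": cm.sensitivity,
                             "hausdorff_mm": cm.hausdorff_mm,
                             "mavd_cm3": cm.mavd_cm3,
                             "volume_auto_cm3": cm.volume_auto_cm3,
                             "volume_manual_cm3": cm.volume_manual_cm3})
                if name == "mean":
                    v_auto.append(cm.volume_auto_cm3)
                    v_manual.append(cm.volume_manual_cm3)
    per_case = pd.DataFrame(rows)
    summary = (
        per_case.groupby("map")[["jaccard", "dice", "sensitivity",
                                 "hausdorff_mm", "mavd_cm3"]]
        .agg(["mean", "std"])
    )
    report = agreement(v_auto, v_manual) if len(v_auto) >= 3 else None
    return {"per_case": per_case, "summary": summary, "plan": plan,
            "agreement": report, "folds": fold_outputs}


def scaled_benchmark(seed=1, n_subjects=12, epochs=15, batch_size=8,
                     width_multiplier=0.125, n_levels=7):
    """CPU-scale end-to-end experiment: a 12-subject phantom cohort,
    one width-1/8 model trained briefly on 10 subjects (two of which
    steer early stopping) and scored on the 2 held-out subjects.

    The batch size is scaled down with the cohort (32 would give only
    four updates per epoch here).  Returns mean held-out Dice per map
    plus the per-case results.
    """
    cfg = PhantomConfig(n_subjects=n_subjects, master_seed=seed)
    stacks, manifest = generate_dataset(cfg)
    plan = stratified_group_folds(manifest, max(2, n_subjects // 2), seed)
    train_ids, test_ids = plan.split(0)
    tc = TrainingConfig(seed=seed, augmentation=False, max_epochs=epochs,
                        early_stop_patience=max(1, epochs - 1),
                        batch_size=batch_size)
    out = run_fold(stacks, train_ids, test_ids, tc,
                   width_multiplier=width_multiplier, n_levels=n_levels)
    mean_dice = {name: float(np.mean([c.dice for c in cases]))
                 for name, cases in out["results"].items() if cases}
    return {"mean_dice": mean_dice, "results": out["results"],
            "model": out["model"], "stacks": stacks, "manifest": manifest,
            "history": out["history"], "info": out["info"],
            "train_ids": train_ids, "test_ids": test_ids}
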