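"""Train a miniature model end to end and score the held-out subject.

Uses a small 32x32 cohort and a narrow 4-level network so the whole
script runs in about ten seconds; the full scaled experiment (12
subjects at 64x64, width-1/8, 7 levels, Dice around 0.9) lives in
scripts/acceptance.py.
"""

from simounet import PhantomConfig, TrainingConfig, generate_dataset
from simounet.pipeline import run_fold

config = PhantomConfig(
    n_subjects=6,
    slices_per_subject=(8, 10),
    image_size=(32, 32),
    brain_axis_range_px=(4.0, 7.0),
    skull_gap_px=1.5,
    master_seed=0,
)
stacks, manifest = generate_dataset(config)
subjects = list(manifest["subject_id"])
train_ids, test_ids = subjects[:5], subjects[5:]

cfg = TrainingConfig(seed=0, augmentation=False, batch_size=8,
                     max_epochs=30, early_stop_patience=29)
out = run_fold(stacks, train_ids, test_ids, cfg,
               width_multiplier=1 / 8, n_levels=4, val_fraction=0.25)
print(out["history"][["epoch", "train_loss", "val_loss", "val_dice"]]
      .tail(5).to_string(index=False))

for cm in out["results"]["mean"]:
    print(f"\nheld-out {cm.subject_id} (mean fusion): Dice {cm.dice:.3f}, "
          f"Jaccard {cm.jaccard:.3f}, HD {cm.hausdorff_mm:.1f} mm, "
          f"volume auto/manual {cm.volume_auto_cm3:.2f}/{cm.volume_manual_cm3:.2f} cm^3")
# Train and validation losses fall steadily toward the -5 optimum of the
# five-head objective.  Thirty epochs on five tiny subjects only gets the
# held-out Dice to roughly 0.5 — the scaled experiment with more subjects,
# larger slices and a deeper model reaches about 0.9.
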