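"""Build the single-input multi-output network and run a forward pass.

The default deep spec has 8 contracting levels, 15 side outputs and 5
prediction heads; a width multiplier scales every channel count, which
is how the CPU-scale experiments stay tractable.
"""

import numpy as np

from simounet import build_simou_spec, build_simo_unet_spec, instantiate, predict

spec = build_simou_spec()
print(f"default spec: {spec.n_levels} levels, {spec.n_side_outputs} side outputs, "
      f"{spec.n_heads} heads, channels {spec.channels}")

# the plain 5-level U-Net wrapped with the same side-output pattern
unet = build_simo_unet_spec()
print(f"SIMO U-Net:   {unet.n_levels} levels, {unet.n_side_outputs} side outputs, "
      f"{unet.n_heads} heads")

# a thin variant small enough to execute here: width 1/8, 64x64 input
small = build_simou_spec((64, 64, 1), width_multiplier=0.125, n_levels=7)
model = instantiate(small, seed=0)
images = np.random.default_rng(0).random((2, 64, 64)).astype(np.float32)
preds = predict(model, images)
print(f"forward pass: five probability maps of shape {preds.p_f.shape}, "
      f"values in [{preds.stack().min():.3f}, {preds.stack().max():.3f}]")
# Every head emits one foreground-probability map per slice; at random
# initialisation the maps hover near 0.5.
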