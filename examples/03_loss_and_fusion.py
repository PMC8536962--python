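"""The hybrid loss and prediction-map fusion on closed-form cases.

The loss adds a foreground-weighted cross-entropy term to a soft Dice
coefficient and negates the sum, so a perfect prediction scores -1.
Fusion combines the five head maps per pixel (mean / median / max)
into a within-network ensemble.
"""

import math

import numpy as np

from simounet import fuse, hybrid_loss, total_objective

truth = np.ones((8, 8))
print(f"loss at perfect prediction:  {hybrid_loss(truth, truth):+.6f}  (minimum)")
half = np.full((8, 8), 0.5)
print(f"loss at uniform 0.5:         {hybrid_loss(half, truth):+.6f}  "
      f"(closed form {-(0.5 * math.log(0.5) + 2 / 3):+.6f})")

# the training objective weights the loss of each of the five heads
rng = np.random.default_rng(0)
preds = {h: rng.random((1, 8, 8)) for h in ("d_ux", "d_u", "u", "d", "f")}
binary = (rng.random((1, 8, 8)) > 0.5).astype(float)
print(f"deep-supervision objective (equal weights): "
      f"{total_objective(preds, binary, (1,) * 5):+.4f}")

# fusion of five maps at one pixel
stack = np.array([0.1, 0.2, 0.3, 0.4, 0.5]).reshape(5, 1, 1)
for op in ("mean", "median", "max"):
    print(f"fuse {op:6s} of (0.1..0.5): {fuse(stack, op).values[0, 0]:.2f}")
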