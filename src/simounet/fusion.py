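"""Ensemble fusion of the five prediction maps, and binarisation.

Fusion acts per pixel on probabilities *before* thresholding: the mean
(P_AVG), median (P_MED, the 3rd order statistic of five) or maximum
(P_MAX) over the five head outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import PredictionSet

__all__ = ["FusedMap", "FUSION_OPS", "fuse", "binarize"]

FUSION_OPS = {
    "mean": lambda s: s.mean(axis=0),
    "median": lambda s: np.median(s, axis=0),
    "max": lambda s: s.max(axis=0),
}

_ALIASES = {"avg": "mean", "med": "median"}


@dataclass
class FusedMap:
    values: np.ndarray    # (..., H, W) in [0, 1]
    op_name: str
    source: str = ""


def fuse(predictions, op_name: str) -> FusedMap:
    """Per-pixel mean / median / max over the five prediction maps.

    ``predictions`` may be a PredictionSet, a dict of the five maps, or
    a (5, ..., H, W) array.
    """
    op_name = _ALIASES.get(op_name, op_name)
    if op_name not in FUSION_OPS:
        raise ValueError(
            f"unknown fusion op {op_name!r}; valid: {sorted(FUSION_OPS)} "
            f"(aliases: {sorted(_ALIASES)})"
        )
    if isinstance(predictions, PredictionSet):
        stacked = predictions.stack()
        source = "prediction_set"
    elif isinstance(predictions, dict):
        stacked = np.stack([np.asarray(v) for v in predictions.values()], axis=0)
        source = "dict"
    else:
        stacked = np.asarray(predictions)
        source = "array"
    if stacked.shape[0] != 5:
        raise ValueError(f"expected five maps, got {stacked.shape[0]}")
    return FusedMap(values=FUSION_OPS[op_name](stacked), op_name=op_name, source=source)


def binarize(prob_map, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: 1 where value >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    values = prob_map.values if isinstance(prob_map, FusedMap) else np.asarray(prob_map)
    return (values >= threshold).astype(np.uint8)
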