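"""Evaluation suite: overlap metrics, Hausdorff distance in mm, brain
volume in cm3, per-case aggregation and volume-agreement statistics.

Overlap metrics (Jaccard, Dice, sensitivity) and the Hausdorff distance
are computed per 2D slice on slices whose ground truth contains
foreground, then averaged over the case; volumes integrate every slice
of the stack (foreground voxel count x dx x dy x dz).  Undefined values
(empty masks) are flagged as missing and logged, never silently zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "CaseMetrics",
    "AgreementReport",
    "confusion_counts",
    "overlap_metrics",
    "hausdorff_mm",
    "brain_volume_cm3",
    "evaluate_case",
    "agreement",
    "summarize_cases",
]


@dataclass
class CaseMetrics:
    jaccard: float
    dice: float
    sensitivity: float
    hausdorff_mm: float          # NaN when undefined on every slice
    mavd_cm3: float
    volume_auto_cm3: float
    volume_manual_cm3: float
    n_slices_evaluated: int
    subject_id: str = ""


@dataclass
class AgreementReport:
    r_squared: float             # NaN when a list has zero variance
    mean_diff_cm3: float
    loa_low_cm3: float
    loa_high_cm3: float
    n_cases: int


def _check_binary(arr, name):
    arr = np.asarray(arr)
    if not np.all(np.isin(np.unique(arr), [0, 1])):
        raise ValueError(f"{name} must be binary")
    return arr.astype(bool)


def confusion_counts(pred_mask, truth_mask):
    """Elementwise (TP, FP, FN, TN) between two binary masks."""
    pred = _check_binary(pred_mask, "pred_mask")
    truth = _check_binary(truth_mask, "truth_mask")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return tp, fp, fn, tn


def overlap_metrics(tp, fp, fn):
    """(Jaccard, Dice, sensitivity) from confusion counts.

    J = TP/(TP+FP+FN); D = 2TP/(2TP+FP+FN); Sen = TP/(TP+FN).
    Undefined ratios are returned as None (and logged).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    union = tp + fp + fn
    if union > 0:
        jaccard = tp / union
        dice = 2 * tp / (2 * tp + fp + fn)
    else:
        jaccard = dice = None
        logger.warning("overlap_metrics: empty union, J/D undefined")
    if tp + fn > 0:
        sen = tp / (tp + fn)
    else:
        sen = None
        logger.warning("overlap_metrics: empty truth, sensitivity undefined")
    return jaccard, dice, sen


def hausdorff_mm(mask_a, mask_b, pixel_spacing_mm):
    """Symmetric Hausdorff distance between two 2D masks, in mm.

    Foreground pixel coordinates are scaled by (dx, dy) before the
    max-min distance; None when either mask is empty.
    """
    a = _check_binary(mask_a, "mask_a")
    b = _check_binary(mask_b, "mask_b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    dx, dy = pixel_spacing_mm
    # rows step by dy (the row axis is the physical y axis), columns by dx
    scale = np.array([dy, dx], dtype=float)
    pa = np.argwhere(a) * scale
    pb = np.argwhere(b) * scale
    if len(pa) == 0 or len(pb) == 0:
        logger.warning("hausdorff_mm: empty mask, distance undefined")
        return None
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


def brain_volume_cm3(mask_stack, pixel_spacing_mm, slice_thickness_mm):
    """Foreground voxel count x dx x dy x dz, converted mm3 -> cm3."""
    stack = _check_binary(mask_stack, "mask_stack")
    dx, dy = pixel_spacing_mm
    if dx <= 0 or dy <= 0 or slice_thickness_mm <= 0:
        raise ValueError("geometry must be strictly positive")
    return float(np.count_nonzero(stack) * dx * dy * slice_thickness_mm / 1000.0)


def evaluate_case(prob_maps, truth_stack, pixel_spacing_mm, slice_thickness_mm,
                  threshold: float = 0.5, subject_id: str = ""):
    """Per-case metrics from already-fused per-slice probability maps.

    Slices with empty ground truth are excluded from the overlap/HD
    averages (undefined denominators) but both stacks contribute fully
    to the volumes.  Returns None (logged) when no slice has truth
    foreground.
    """
    from .fusion import binarize

    prob_maps = np.asarray(prob_maps)
    truth = _check_binary(truth_stack, "truth_stack")
    if prob_maps.shape != truth.shape:
        raise ValueError(f"shape mismatch: {prob_maps.shape} vs {truth.shape}")
    pred = binarize(prob_maps, threshold)
    fg_slices = [s for s in range(truth.shape[0]) if truth[s].any()]
    if not fg_slices:
        logger.warning("evaluate_case(%s): no foreground slice in truth; case excluded",
                       subject_id)
        return None
    js, ds, sens, hds = [], [], [], []
    for s in fg_slices:
        tp, fp, fn, _ = confusion_counts(pred[s], truth[s])
        j, d, sen = overlap_metrics(tp, fp, fn)
        js.append(j)
        ds.append(d)
        sens.append(sen)
        hd = hausdorff_mm(pred[s], truth[s], pixel_spacing_mm)
        if hd is not None:
            hds.append(hd)
    v_auto = brain_volume_cm3(pred, pixel_spacing_mm, slice_thickness_mm)
    v_manual = brain_volume_cm3(truth, pixel_spacing_mm, slice_thickness_mm)
    return CaseMetrics(
        jaccard=float(np.mean(js)),
        dice=float(np.mean(ds)),
        sensitivity=float(np.mean(sens)),
        hausdorff_mm=float(np.mean(hds)) if hds else float("nan"),
        mavd_cm3=abs(v_auto - v_manual),
        volume_auto_cm3=v_auto,
        volume_manual_cm3=v_manual,
        n_slices_evaluated=len(fg_slices),
        subject_id=subject_id,
    )


def agreement(volumes_auto, volumes_manual) -> AgreementReport:
    """Volume-agreement statistics: squared Pearson correlation and
    Bland-Altman mean difference with 1.96-sd limits of agreement
    (differences taken auto - manual; sample sd, n-1)."""
    auto = np.asarray(volumes_auto, dtype=float)
    manual = np.asarray(volumes_manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("volume lists must be 1D and equal length")
    n = len(auto)
    if n < 3:
        raise ValueError("need at least 3 cases")
    if np.ptp(auto) == 0 or np.ptp(manual) == 0:
        r2 = float("nan")
        logger.warning("agreement: zero variance, r_squared undefined")
    else:
        r2 = float(pearsonr(auto, manual)[0] ** 2)
    d = auto - manual
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        r_squared=r2,
        mean_diff_cm3=mean_diff,
        loa_low_cm3=mean_diff - 1.96 * sd,
        loa_high_cm3=mean_diff + 1.96 * sd,
        n_cases=n,
    )


def summarize_cases(cases, group_key=None):
    """Mean +/- sd table over CaseMetrics, optionally grouped by a
    dict subject_id -> label (e.g. fusion op or head name)."""
    import pandas as pd

    rows = []
    for c in cases:
        rows.append(
            {
                "subject_id": c.subject_id,
                "group": group_key.get(c.subject_id, "") if group_key else "",
                "jaccard": c.jaccard,
                "dice": c.dice,
                "sensitivity": c.sensitivity,
                "hausdorff_mm": c.hausdorff_mm,
                "mavd_cm3": c.mavd_cm3,
                "volume_auto_cm3": c.volume_auto_cm3,
                "volume_manual_cm3": c.volume_manual_cm3,
            }
        )
    return pd.DataFrame(rows)
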