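"""Synthetic foetal-brain-like phantom volumes with ground-truth masks.

Each subject is a stack of 2D slices containing an elliptical "brain"
inside a brighter "skull" ring and surrounding head tissue.  The brain
area follows a smooth axial profile — maximal mid-stack, shrinking
toward both ends — and the brain/tissue contrast degrades toward the
end slices, emulating the two regimes that make real foetal MR stacks
hard: tiny, low-contrast brains on the top/bottom slices, and
skull-adjacent boundaries mid-stack.  Optional ghosting adds a faint
shifted replica of the head, as motion does during acquisition.

Everything is a pure function of (config, master_seed, subject_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "VolumeStack",
    "generate_subject",
    "generate_dataset",
    "augment",
    "apply_transform",
    "compute_strata",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    pass


# intensity levels (arbitrary units, image roughly in [0, 1])
_BG = 0.08          # amniotic fluid / outside head
_TISSUE = 0.35      # head tissue between brain and skull
_BRAIN = 0.75       # brain at full contrast
_SKULL = 0.95       # skull ring
_RING_W = 2.0       # skull ring width, px
_END_AREA_SCALE = 0.30   # linear size of the brain at the end slices
_GHOST_GAIN = 0.15


@dataclass
class PhantomConfig:
    """Generation parameters for a synthetic cohort.

    Defaults emulate a small clinical-like study: 64x64 slices at
    1.5 mm in-plane resolution and 2.3 mm slice thickness (the middle
    of the 2.0-2.6 mm range typical of foetal acquisitions), 12-18
    slices per subject, mid-slice brain semi-axes of 8-18 px
    (12-27 mm), brain/tissue contrast at the end slices reduced to 35%
    of the mid-slice contrast, and ghosting on 15% of slices.
    """

    n_subjects: int = 12
    slices_per_subject: tuple = (12, 18)
    image_size: tuple = (64, 64)
    pixel_spacing_mm: tuple = (1.5, 1.5)
    slice_thickness_mm: float = 2.3
    brain_axis_range_px: tuple = (8.0, 18.0)
    area_profile_exponent: float = 0.7
    skull_gap_px: float = 2.0
    contrast_falloff: float = 0.35
    noise_sd: float = 0.04
    ghosting_prob: float = 0.15
    master_seed: int = 0

    def validate(self):
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ConfigurationError("image_size must be positive")
        if self.pixel_spacing_mm[0] <= 0 or self.pixel_spacing_mm[1] <= 0:
            raise ConfigurationError("pixel_spacing_mm must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ConfigurationError("slice_thickness_mm must be > 0")
        lo, hi = self.brain_axis_range_px
        if not 0 < lo <= hi:
            raise ConfigurationError("brain_axis_range_px must be positive and ordered")
        if hi + max(self.skull_gap_px, 0.0) + _RING_W + 2 > min(h, w) / 2:
            raise ConfigurationError(
                "brain_axis_range_px: maximal brain semi-axis plus skull_gap_px "
                f"and ring width does not fit a {h}x{w} image"
            )
        if not 0.0 <= self.ghosting_prob <= 1.0:
            raise ConfigurationError("ghosting_prob must be in [0, 1]")
        if self.slices_per_subject[0] < 3:
            raise ConfigurationError("slices_per_subject must be >= 3")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        return self


@dataclass
class VolumeStack:
    """One case: ordered 2D slices with physical geometry and an
    optional ground-truth mask stack of identical shape."""

    slices: np.ndarray                 # (S, H, W) float32
    pixel_spacing_mm: tuple            # (dx, dy)
    slice_thickness_mm: float
    subject_id: str
    mask: np.ndarray | None = None     # (S, H, W) uint8 in {0,1}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float32)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("slices must be a (S, H, W) array with S >= 1")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.slices.shape:
                raise ValueError("mask shape must match slices")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("mask must contain only {0, 1}")
            self.mask = self.mask.astype(np.uint8)
        dx, dy = self.pixel_spacing_mm
        if dx <= 0 or dy <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("geometry must be strictly positive")

    @property
    def n_slices(self):
        return self.slices.shape[0]


def _axial_profile(t, exponent, floor):
    """Smooth unimodal profile on [0,1]: `floor` at the ends, 1 at t=0.5."""
    return floor + (1.0 - floor) * (4.0 * t * (1.0 - t)) ** exponent


def _ellipse_mask(h, w, cy, cx, a, b, phi):
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy - cy, xx - cx
    c, s = np.cos(phi), np.sin(phi)
    u = c * x + s * y
    v = -s * x + c * y
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_subject(config: PhantomConfig, subject_index: int) -> VolumeStack:
    """Deterministically generate one subject's volume and mask."""
    config.validate()
    if subject_index < 0:
        raise ValueError("subject_index must be >= 0")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.master_seed) % (2**31), int(subject_index)])
    )
    h, w = config.image_size
    lo_s, hi_s = config.slices_per_subject
    n_slices = int(rng.integers(lo_s, hi_s + 1))
    a = rng.uniform(*config.brain_axis_range_px)
    b = rng.uniform(*config.brain_axis_range_px)
    phi = rng.uniform(0.0, np.pi)
    outer = max(a, b) + max(config.skull_gap_px, 0.0) + _RING_W + 1
    cy = rng.uniform(outer, h - outer)
    cx = rng.uniform(outer, w - outer)

    slices = np.empty((n_slices, h, w), dtype=np.float32)
    masks = np.empty((n_slices, h, w), dtype=np.uint8)
    for s in range(n_slices):
        t = (s + 0.5) / n_slices
        scale = _axial_profile(t, config.area_profile_exponent, _END_AREA_SCALE)
        contrast = _axial_profile(t, 1.0, config.contrast_falloff)
        brain = _ellipse_mask(h, w, cy, cx, a * scale, b * scale, phi)
        gap = config.skull_gap_px
        skull_in = _ellipse_mask(h, w, cy, cx, a * scale + gap, b * scale + gap, phi)
        skull_out = _ellipse_mask(
            h, w, cy, cx, a * scale + gap + _RING_W, b * scale + gap + _RING_W, phi
        )
        img = np.full((h, w), _BG, dtype=np.float32)
        img[skull_out] = _SKULL
        img[skull_in] = _TISSUE
        img[brain] = _TISSUE + (_BRAIN - _TISSUE) * contrast
        if rng.random() < config.ghosting_prob:
            shift = int(rng.integers(4, max(5, h // 6)))
            img = img + _GHOST_GAIN * np.roll(img, shift, axis=0)
        img = img + rng.normal(0.0, config.noise_sd, size=(h, w))
        slices[s] = img
        masks[s] = brain.astype(np.uint8)

    mid = masks[n_slices // 2].sum()
    return VolumeStack(
        slices=slices,
        mask=masks,
        pixel_spacing_mm=tuple(config.pixel_spacing_mm),
        slice_thickness_mm=config.slice_thickness_mm,
        subject_id=f"S{subject_index:03d}",
        metadata={"mid_slice_area_px": int(mid), "n_slices": n_slices},
    )


def compute_strata(mid_areas, labels=("q1", "q2", "q3", "q4")):
    """Rank-based quartile labels of mid-slice brain area (a size /
    gestational-age surrogate); group sizes differ by at most one."""
    mid_areas = np.asarray(mid_areas)
    n = len(mid_areas)
    order = np.argsort(mid_areas, kind="stable")
    strata = np.empty(n, dtype=object)
    k = len(labels)
    for pos, idx in enumerate(order):
        strata[idx] = labels[pos * k // n]
    return strata


def generate_dataset(config: PhantomConfig, out_dir=None, overwrite=False,
                     fmt="nifti"):
    """Generate the full cohort and its manifest.

    Returns (stacks, manifest).  The manifest records subject_id,
    n_slices, mid-slice brain area and a quartile stratum label used
    for stratified subject-grouped folding.  With ``out_dir`` the
    volumes and manifest are also written to disk.
    """
    config.validate()
    stacks = [generate_subject(config, i) for i in range(config.n_subjects)]
    areas = [s.metadata["mid_slice_area_px"] for s in stacks]
    manifest = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in stacks],
            "n_slices": [s.n_slices for s in stacks],
            "mid_slice_area_px": areas,
            "stratum": compute_strata(areas),
        }
    )
    if out_dir is not None:
        from . import io as sio

        out_dir = Path(out_dir)
        if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
            raise FileExistsError(
                f"output directory {out_dir} is not empty; pass overwrite=True"
            )
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in stacks:
            if fmt == "nifti":
                sio.write_volume(s, out_dir / f"{s.subject_id}.nii.gz")
            else:
                sio.write_volume(s, out_dir / s.subject_id)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return stacks, manifest


# -- augmentation --------------------------------------------------------


def apply_transform(image, mask, theta_deg=0.0, zoom=1.0, flip_h=False,
                    flip_v=False):
    """Apply a rotation / zoom / flip jointly to an image and its mask.

    Linear interpolation for the image, nearest for the mask with a 0.5
    re-binarisation; the output keeps the input shape (zoom crops or
    zero-pads around the centre); out-of-bounds pixels are background 0.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    img = image.astype(np.float32)
    msk = mask.astype(np.float32)
    if theta_deg % 360 != 0:
        img = ndimage.rotate(img, theta_deg, reshape=False, order=1, mode="constant", cval=0.0)
        msk = ndimage.rotate(msk, theta_deg, reshape=False, order=0, mode="constant", cval=0.0)
    if zoom != 1.0:
        img = _zoom_keep_shape(img, zoom, order=1)
        msk = _zoom_keep_shape(msk, zoom, order=0)
    if flip_h:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if flip_v:
        img, msk = img[::-1, :], msk[::-1, :]
    return np.ascontiguousarray(img), np.ascontiguousarray(msk >= 0.5).astype(np.uint8)


def _zoom_keep_shape(arr, factor, order):
    h, w = arr.shape
    z = ndimage.zoom(arr, factor, order=order, mode="constant", cval=0.0)
    zh, zw = z.shape
    out = np.zeros_like(arr)
    # centre-crop or centre-pad back to (h, w)
    sy, sx = max(0, (zh - h) // 2), max(0, (zw - w) // 2)
    dy, dx = max(0, (h - zh) // 2), max(0, (w - zw) // 2)
    ch, cw = min(h, zh), min(w, zw)
    out[dy:dy + ch, dx:dx + cw] = z[sy:sy + ch, sx:sx + cw]
    return out


def augment(image, mask, rng, theta_deg=None, zoom=None, flip_h=None, flip_v=None):
    """One random augmentation of an (image, mask) pair.

    Samples (unless overridden) a rotation in [-180, 180] degrees, a
    zoom factor in [0.1, 2.0] and independent horizontal/vertical
    flips, applied identically to image and mask.
    """
    if theta_deg is None:
        theta_deg = float(rng.uniform(-180.0, 180.0))
    if zoom is None:
        zoom = float(rng.uniform(0.1, 2.0))
    if flip_h is None:
        flip_h = bool(rng.random() < 0.5)
    if flip_v is None:
        flip_v = bool(rng.random() < 0.5)
    return apply_transform(image, mask, theta_deg, zoom, flip_h, flip_v)
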